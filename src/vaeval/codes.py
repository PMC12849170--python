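"""Cause-of-death code handling.

This module owns the code-level plumbing of the pipeline:

* parsing and normalizing ICD-10 codes;
* assigning deaths to age strata (neonate / child / adult);
* mapping ICD-10 (and WHO-VA-2016) codes to CGHR-10 cause categories through
  inclusive code ranges, one map per age stratum;
* grouping ICD-10 codes into CMEA-10 agreement groups, the unit at which two
  physicians' assignments are judged to agree.

CGHR-10 is a compact cause list: 19 adult, 10 child, and 7 neonatal categories.
CMEA-10 groups are ranges of clinically related ICD-10 codes; they are finer
than (or equal to) the CGHR-10 ranges in the default resource, so two codes in
the same CMEA-10 group always map to the same CGHR-10 category.

Code ordering
-------------
Ranges are inclusive on both ends and compared in conventional ICD-10 tabular
order: letter, then the two digits numerically, then the optional subcode
(numeric subcodes numerically, others lexicographically).  A bare three
character code sorts before any of its subcoded children ("J45" < "J45.0"),
and a range ending at a bare code includes all of that code's children
("J45.9" is inside A00–J45).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional

from .errors import AgeOutOfRangeError, ConfigurationError, InvalidCodeError

__all__ = [
    "AgeStratum",
    "Icd10Code",
    "CghrCategory",
    "CodeMapTable",
    "CmeaGroupTable",
    "MapEntry",
    "CmeaEntry",
    "normalize_icd10",
    "assign_age_stratum",
    "map_to_cghr10",
    "cmea_group_of",
    "enumerate_codes",
    "DAYS_PER_YEAR",
    "DAYS_PER_MONTH",
    "NEONATE_UPPER_DAYS",
    "CHILD_UPPER_DAYS",
    "ADULT_UPPER_DAYS",
]

# Calendar conventions used throughout the package.
DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = 30.44

#: neonate: age_days < 28
NEONATE_UPPER_DAYS = 28
#: child: 28 days <= age_days < 12 years
CHILD_UPPER_DAYS = int(12 * DAYS_PER_YEAR)  # 4383
#: adult: 12 years <= age, completed age <= 69 years
ADULT_UPPER_DAYS = int(70 * DAYS_PER_YEAR)  # 25567


class AgeStratum(str, Enum):
    """The three age strata of the study design."""

    NEONATE = "neonate"
    CHILD = "child"
    ADULT = "adult"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def assign_age_stratum(age_days: int) -> AgeStratum:
    """Assign a death to its age stratum from age at death in days.

    Boundaries: under 28 days is neonatal; 28 days up to (exclusive) 12 years
    is child; 12 years up to completed age 69 is adult.  Ages of 70+ completed
    years are outside the study design and raise :class:`AgeOutOfRangeError`
    (callers exclude and log such records rather than coercing them).
    """
    age_days = int(age_days)
    if age_days < 0:
        raise AgeOutOfRangeError(f"negative age at death: {age_days} days")
    if age_days < NEONATE_UPPER_DAYS:
        return AgeStratum.NEONATE
    if age_days < CHILD_UPPER_DAYS:
        return AgeStratum.CHILD
    if age_days < ADULT_UPPER_DAYS:
        return AgeStratum.ADULT
    raise AgeOutOfRangeError(
        f"age {age_days} days exceeds the adult upper bound of 69 completed years"
    )


# --------------------------------------------------------------------------
# ICD-10 codes
# --------------------------------------------------------------------------

_ICD_RE = re.compile(r"^([A-Z])(\d{2})(?:\.([A-Z0-9]{1,2}))?$")


@dataclass(frozen=True)
class Icd10Code:
    """An ICD-10 code in raw and normalized form.

    ``normalized`` is one uppercase letter, two digits, and an optional dot
    plus 1-2 alphanumeric subcode characters, e.g. ``"J45"`` or ``"J45.9"``.
    """

    raw: str
    normalized: str

    def __str__(self) -> str:
        return self.normalized

    @property
    def letter(self) -> str:
        return self.normalized[0]

    @property
    def digits(self) -> int:
        return int(self.normalized[1:3])

    @property
    def subcode(self) -> Optional[str]:
        return self.normalized[4:] if len(self.normalized) > 3 else None


def normalize_icd10(raw: str) -> Icd10Code:
    """Parse and canonicalize an ICD-10 code.

    Case and separator variants are canonicalized: ``"j45.9"``, ``"J45-9"``,
    ``"J45 9"`` and ``"J459"`` all normalize to ``"J45.9"``.  Normalization is
    idempotent.  Malformed codes raise :class:`InvalidCodeError` naming the
    offending text.
    """
    if raw is None or not str(raw).strip():
        raise InvalidCodeError("empty ICD-10 code")
    s = str(raw).strip().upper()
    for sep in (" ", "-", "_", "/"):
        s = s.replace(sep, "")
    if "." not in s and 4 <= len(s) <= 5:
        s = s[:3] + "." + s[3:]
    if not _ICD_RE.match(s):
        raise InvalidCodeError(f"not a valid ICD-10 code: {raw!r}")
    return Icd10Code(raw=str(raw), normalized=s)


def _sub_key(sub: Optional[str]) -> tuple:
    """Sort key for an ICD-10 subcode: absent < numeric < other."""
    if sub is None or sub == "":
        return (-1, 0, "")
    if sub.isdigit():
        return (0, int(sub), "")
    return (1, 0, sub)


def icd_sort_key(code: str) -> tuple:
    """Total order on normalized ICD-10 codes; "J45" sorts before "J45.0"."""
    c = normalize_icd10(code)
    return (c.letter, c.digits, _sub_key(c.subcode))


def _icd_lower_key(code: str) -> tuple:
    """Key of a range start: a bare code covers all its subcoded children."""
    c = normalize_icd10(code)
    sub = _sub_key(c.subcode) if c.subcode else (-2, 0, "")
    return (c.letter, c.digits, sub)


def _icd_upper_key(code: str) -> tuple:
    """Key of an inclusive range end: a bare code covers all its children."""
    c = normalize_icd10(code)
    sub = _sub_key(c.subcode) if c.subcode else (2, 0, "")
    return (c.letter, c.digits, sub)


# WHO-VA-2016 cause codes are dotted numeric tokens such as "01.05".  They are
# ordered numerically segment by segment, with the same bare-prefix-covers-
# children convention as ICD-10 ranges.

def _whova_parts(code: str) -> tuple:
    parts = []
    for p in str(code).strip().upper().split("."):
        parts.append((0, int(p), "") if p.isdigit() else (1, 0, p))
    return tuple(parts)


def _whova_key(code: str, bound: str = "point") -> tuple:
    sentinel = {"point": (-1, 0, ""), "lower": (-2, 0, ""), "upper": (2, 0, "")}[bound]
    return _whova_parts(code) + (sentinel,)


def _keys_for(system: str, code: str) -> tuple:
    """(point, lower, upper) keys for a code under the given coding system."""
    if system == "ICD10":
        return icd_sort_key(code), _icd_lower_key(code), _icd_upper_key(code)
    if system == "WHOVA2016":
        return (
            _whova_key(code, "point"),
            _whova_key(code, "lower"),
            _whova_key(code, "upper"),
        )
    raise ConfigurationError(f"unknown code system: {system!r}")


def enumerate_codes(start: str, end: str) -> Iterator[str]:
    """Enumerate the three-character ICD-10 codes in an inclusive range.

    Both endpoints must be bare three-character codes (the granularity at
    which the shipped resources define ranges).  The enumeration walks the
    tabular order across letters, e.g. A98..B02.
    """
    s, e = normalize_icd10(start), normalize_icd10(end)
    if s.subcode or e.subcode:
        raise ConfigurationError(
            f"enumerate_codes requires bare 3-character endpoints, got {start!r}-{end!r}"
        )
    a = (ord(s.letter) - 65) * 100 + s.digits
    b = (ord(e.letter) - 65) * 100 + e.digits
    if a > b:
        raise ConfigurationError(f"inverted code range {start!r}-{end!r}")
    for v in range(a, b + 1):
        yield f"{chr(65 + v // 100)}{v % 100:02d}"


# --------------------------------------------------------------------------
# CGHR-10 categories and code-range tables
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CghrCategory:
    """One CGHR-10 cause category, scoped to an age stratum."""

    id: str
    label: str
    age_stratum: AgeStratum


@dataclass(frozen=True)
class MapEntry:
    source_system: str  # "ICD10" | "WHOVA2016"
    range_start: str
    range_end: str
    age_stratum: AgeStratum
    target: str  # CghrCategory id


@dataclass(frozen=True)
class CmeaEntry:
    group_id: str
    range_start: str
    range_end: str


def _check_nonoverlap(entries, keyfn_lower, keyfn_upper, context: str) -> None:
    ordered = sorted(entries, key=lambda e: keyfn_lower(e))
    for prev, nxt in zip(ordered, ordered[1:]):
        if keyfn_lower(nxt) <= keyfn_upper(prev):
            raise ConfigurationError(
                f"overlapping code ranges in {context}: "
                f"{prev.range_start}-{prev.range_end} and {nxt.range_start}-{nxt.range_end}"
            )


class CodeMapTable:
    """Inclusive code ranges mapping source-system codes to CGHR-10 categories.

    Within one (source_system, age_stratum) the ranges must be non-overlapping
    and every target must exist in the category resource for that stratum;
    both are validated at construction.
    """

    def __init__(
        self,
        entries: Iterable[MapEntry],
        categories: dict[AgeStratum, list[CghrCategory]],
    ):
        self.entries = list(entries)
        self.categories = categories
        self._cat_index = {
            (c.age_stratum, c.id): c for cats in categories.values() for c in cats
        }
        for s, cats in categories.items():
            ids = [c.id for c in cats]
            if len(ids) != len(set(ids)):
                raise ConfigurationError(f"duplicate category ids in stratum {s}")
        by_key: dict[tuple, list[MapEntry]] = {}
        for e in self.entries:
            if (e.age_stratum, e.target) not in self._cat_index:
                raise ConfigurationError(
                    f"map target {e.target!r} not a {e.age_stratum.value} category"
                )
            by_key.setdefault((e.source_system, e.age_stratum), []).append(e)
        for (system, stratum), group in by_key.items():
            _check_nonoverlap(
                group,
                lambda e, s=system: _keys_for(s, e.range_start)[1],
                lambda e, s=system: _keys_for(s, e.range_end)[2],
                f"map ({system}, {stratum.value})",
            )
        self._by_key = by_key
        # precomputed (lo, hi, target) triples so lookup avoids reparsing
        self._ranges = {
            key: [
                (
                    _keys_for(key[0], e.range_start)[1],
                    _keys_for(key[0], e.range_end)[2],
                    e.target,
                )
                for e in group
            ]
            for key, group in by_key.items()
        }

    @classmethod
    def from_csv(
        cls, path, categories: dict[AgeStratum, list[CghrCategory]]
    ) -> "CodeMapTable":
        """Read a map from CSV with header
        ``source_system,range_start,range_end,age_stratum,target_id``."""
        entries = []
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                system = row["source_system"].strip()
                start, end = row["range_start"].strip(), row["range_end"].strip()
                if system == "ICD10":
                    start = normalize_icd10(start).normalized
                    end = normalize_icd10(end).normalized
                entries.append(
                    MapEntry(
                        source_system=system,
                        range_start=start,
                        range_end=end,
                        age_stratum=AgeStratum(row["age_stratum"].strip()),
                        target=row["target_id"].strip(),
                    )
                )
        return cls(entries, categories)

    def lookup(
        self, code: str, stratum: AgeStratum, source_system: str = "ICD10"
    ) -> Optional[str]:
        """Return the CGHR-10 category id containing ``code``, or None."""
        point = _keys_for(source_system, code)[0]
        for lo, hi, target in self._ranges.get((source_system, stratum), ()):
            if lo <= point <= hi:
                return target
        return None

    def category(self, stratum: AgeStratum, cat_id: str) -> CghrCategory:
        return self._cat_index[(stratum, cat_id)]

    def ranges_for(
        self, stratum: AgeStratum, target: str, source_system: str = "ICD10"
    ) -> list[tuple[str, str]]:
        """All (start, end) ranges mapping to ``target`` in ``stratum``."""
        return [
            (e.range_start, e.range_end)
            for e in self._by_key.get((source_system, stratum), ())
            if e.target == target
        ]


def map_to_cghr10(
    code, stratum: AgeStratum, table: CodeMapTable, source_system: str = "ICD10"
) -> Optional[CghrCategory]:
    """Map a code to its CGHR-10 category for the given stratum.

    Returns the full :class:`CghrCategory`, or ``None`` (the "unmapped"
    sentinel) when no configured range contains the code.  Unmapped is an
    expected data condition, not an exception: records without a valid
    CGHR-10 category are excluded downstream.
    """
    if isinstance(code, Icd10Code):
        code = code.normalized
    target = table.lookup(code, stratum, source_system)
    return None if target is None else table.category(stratum, target)


class CmeaGroupTable:
    """CMEA-10 agreement groups: inclusive ICD-10 ranges, one group per row set.

    Ranges are non-overlapping across groups (validated), so each code belongs
    to at most one group and group membership is an equivalence relation on
    the codes covered by the table.
    """

    def __init__(self, entries: Iterable[CmeaEntry]):
        self.entries = list(entries)
        _check_nonoverlap(
            self.entries,
            lambda e: _icd_lower_key(e.range_start),
            lambda e: _icd_upper_key(e.range_end),
            "CMEA-10 table",
        )
        self._ranges = [
            (_icd_lower_key(e.range_start), _icd_upper_key(e.range_end), e.group_id)
            for e in self.entries
        ]

    @classmethod
    def from_csv(cls, path) -> "CmeaGroupTable":
        """Read groups from CSV with header ``group_id,range_start,range_end``."""
        entries = []
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                entries.append(
                    CmeaEntry(
                        group_id=row["group_id"].strip(),
                        range_start=normalize_icd10(row["range_start"]).normalized,
                        range_end=normalize_icd10(row["range_end"]).normalized,
                    )
                )
        return cls(entries)

    def lookup(self, code) -> Optional[str]:
        """Return the group id containing ``code``, or None."""
        if isinstance(code, Icd10Code):
            code = code.normalized
        point = icd_sort_key(code)
        for lo, hi, group_id in self._ranges:
            if lo <= point <= hi:
                return group_id
        return None

    @property
    def group_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.group_id, None)
        return list(seen)

    def ranges_of(self, group_id: str) -> list[tuple[str, str]]:
        return [
            (e.range_start, e.range_end)
            for e in self.entries
            if e.group_id == group_id
        ]


def cmea_group_of(code, table: CmeaGroupTable) -> Optional[str]:
    """The CMEA-10 group containing ``code``, or None if outside all ranges."""
    return table.lookup(code)
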