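"""Stratified evaluation orchestration.

Computes PCCC (and, for overall and age-group strata, CSMF accuracy) for
every coder across four stratifications:

* ``overall`` — all records pooled (category labels qualified by stratum so
  cause lists never collide across age groups);
* ``age_group`` — adult / child / neonate;
* ``cause`` — each CGHR-10 category, restricted to records whose reference
  cause equals it (sensitivity-style conditioning; configurable);
* ``age_band`` — fine age bands: 0-6 and 7-27 days for neonates, five-month
  bands from 28 days to one year, then five-year bands up to 69 years.

Low-count cause strata are flagged excluded rather than silently dropped,
and flagging never alters any other stratum's values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .codes import (
    ADULT_UPPER_DAYS,
    DAYS_PER_MONTH,
    DAYS_PER_YEAR,
    AgeStratum,
)
from .errors import ConfigurationError, ContractError
from .metrics import MetricValue, bootstrap_ci, csmf, csmf_accuracy, pccc

__all__ = [
    "AgeBand",
    "AgeBandScheme",
    "EvalConfig",
    "EvalResult",
    "EvalResults",
    "build_age_bands",
    "evaluate_all",
    "exclude_low_n",
    "rank_and_range",
]


@dataclass(frozen=True)
class AgeBand:
    lower_days: float  # inclusive
    upper_days: float  # exclusive
    label: str


class AgeBandScheme:
    """An ordered, contiguous partition of age at death into bands."""

    def __init__(self, bands: Sequence[AgeBand]):
        self.bands = list(bands)
        for prev, nxt in zip(self.bands, self.bands[1:]):
            if nxt.lower_days != prev.upper_days:
                raise ConfigurationError(
                    f"age bands not contiguous at {prev.label!r} -> {nxt.label!r}"
                )

    def band_of(self, age_days: float) -> Optional[str]:
        for b in self.bands:
            if b.lower_days <= age_days < b.upper_days:
                return b.label
        return None

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.bands]


def build_age_bands() -> AgeBandScheme:
    """The default age-band scheme.

    Neonates: 0-6 and 7-27 days.  28 days to one year: five-month bands
    anchored at 28 days (1-5 months, 6-10 months, then the 11-month
    remainder), with one month = 30.44 days.  One year and older: five-year
    bands anchored at one year (1-4, 5-9, 10-14, ... 65-69 years), with one
    year = 365.25 days.  The scheme partitions the full study age range.
    """
    bands = [
        AgeBand(0, 7, "0-6 days"),
        AgeBand(7, 28, "7-27 days"),
        AgeBand(28, 6 * DAYS_PER_MONTH, "1-5 months"),
        AgeBand(6 * DAYS_PER_MONTH, 11 * DAYS_PER_MONTH, "6-10 months"),
        AgeBand(11 * DAYS_PER_MONTH, DAYS_PER_YEAR, "11 months"),
        AgeBand(DAYS_PER_YEAR, 5 * DAYS_PER_YEAR, "1-4 years"),
    ]
    for y in range(5, 70, 5):
        bands.append(
            AgeBand(y * DAYS_PER_YEAR, (y + 5) * DAYS_PER_YEAR, f"{y}-{y + 4} years")
        )
    return AgeBandScheme(bands)


@dataclass
class EvalConfig:
    """Evaluation options.

    ``bootstrap_B`` resamples per interval (1000 for the headline analysis;
    tests may lower it), ``level`` the CI level, ``min_n`` the low-count
    exclusion threshold for cause strata, ``condition_on`` whether per-cause
    PCCC conditions on the reference (physician) or the predicted cause.
    """

    bootstrap_B: int = 1000
    level: float = 0.95
    min_n: int = 10
    seed: int = 0
    condition_on: str = "reference"
    csmf_ci: bool = True

    def __post_init__(self) -> None:
        if self.condition_on not in ("reference", "predicted"):
            raise ConfigurationError("condition_on must be 'reference' or 'predicted'")


@dataclass
class EvalResult:
    """Metrics for one (stratum, coder) cell."""

    kind: str  # overall | age_group | cause | age_band
    key: str
    coder: str
    n: int
    pccc: Optional[MetricValue] = None
    csmf_accuracy: Optional[MetricValue] = None
    excluded: bool = False
    reason: Optional[str] = None


class EvalResults:
    """Container for a full evaluation run."""

    def __init__(self, results: Sequence[EvalResult], config: EvalConfig):
        self.results = list(results)
        self.config = config

    def __iter__(self):
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)

    def select(self, kind: Optional[str] = None, key: Optional[str] = None,
               coder: Optional[str] = None) -> list[EvalResult]:
        out = self.results
        if kind is not None:
            out = [r for r in out if r.kind == kind]
        if key is not None:
            out = [r for r in out if r.key == key]
        if coder is not None:
            out = [r for r in out if r.coder == coder]
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (stratum, coder, metric)."""
        rows = []
        for r in self.results:
            for metric, mv in (("pccc", r.pccc), ("csmf_accuracy", r.csmf_accuracy)):
                if mv is None and not r.excluded:
                    continue
                rows.append(
                    {
                        "kind": r.kind,
                        "key": r.key,
                        "coder": r.coder,
                        "metric": metric,
                        "point": mv.point if mv else np.nan,
                        "raw": (mv.raw if mv and mv.raw is not None else np.nan),
                        "ci_low": mv.ci_low if mv else np.nan,
                        "ci_high": mv.ci_high if mv else np.nan,
                        "n": r.n,
                        "excluded": r.excluded,
                        "reason": r.reason or "",
                        "B": self.config.bootstrap_B,
                        "seed": self.config.seed,
                    }
                )
        return pd.DataFrame(rows)


def _qualified(stratum: pd.Series, cats: pd.Series) -> pd.Series:
    return stratum.astype(str) + ":" + cats.astype(str)


def evaluate_all(
    records: pd.DataFrame,
    coder_outputs: Mapping[str, pd.Series],
    categories: Mapping,
    reference: Optional[pd.Series] = None,
    config: Optional[EvalConfig] = None,
    bands: Optional[AgeBandScheme] = None,
) -> EvalResults:
    """Evaluate every coder against the physician reference across strata.

    ``records`` must carry ``record_id``, ``stratum``, ``age_days`` (and
    ``reference_cghr`` if ``reference`` is not given, as produced by
    :func:`vaeval.workflow.filter_agreed_valid`).  ``coder_outputs`` maps a
    coder name to a Series of CGHR-10 category ids indexed by record id;
    every coder must cover every record.  Returns one :class:`EvalResult`
    per (stratum, coder), with bootstrap intervals attached and low-count
    cause strata flagged per ``config.min_n``.
    """
    config = config or EvalConfig()
    bands = bands or build_age_bands()
    rec = records.set_index("record_id")
    if reference is None:
        if "reference_cghr" not in rec.columns:
            raise ContractError("records lack reference_cghr and no reference given")
        reference = rec["reference_cghr"]
    reference = reference.reindex(rec.index)
    if reference.isna().any():
        raise ContractError("reference does not cover all records")

    aligned: dict[str, pd.Series] = {}
    for name, out in coder_outputs.items():
        out = pd.Series(out).reindex(rec.index)
        if out.isna().any():
            missing = list(rec.index[out.isna()])[:20]
            raise ContractError(f"coder {name!r} missing assignments for {missing}")
        aligned[name] = out

    strata_present = [s for s in AgeStratum if (rec["stratum"] == s.value).any()]
    cat_lists = {s: [c.id for c in categories[s]] for s in strata_present}
    pooled_causes = [f"{s.value}:{c}" for s in strata_present for c in cat_lists[s]]
    n_pooled = len(pooled_causes)

    ref_q = _qualified(rec["stratum"], reference)
    rng = np.random.default_rng(config.seed)
    results: list[EvalResult] = []

    def _pccc_mv(ref_arr, pred_arr, n_cats) -> MetricValue:
        return pccc(
            ref_arr, pred_arr, n_cats,
            bootstrap_B=config.bootstrap_B, level=config.level, rng=rng,
        )

    def _csmfa_mv(ref_arr, pred_arr, cause_list) -> MetricValue:
        ref_v = csmf(ref_arr, cause_list)
        pred_v = csmf(pred_arr, cause_list)
        mv = MetricValue(point=csmf_accuracy(pred_v, ref_v), n=len(ref_arr))
        if config.csmf_ci:
            mv.ci_low, mv.ci_high = bootstrap_ci(
                lambda r, p: csmf_accuracy(csmf(p, cause_list), csmf(r, cause_list)),
                (ref_arr, pred_arr),
                B=config.bootstrap_B, level=config.level, rng=rng,
            )
        return mv

    for name, out in aligned.items():
        out_q = _qualified(rec["stratum"], out)

        # overall
        mv = _pccc_mv(ref_q.to_numpy(), out_q.to_numpy(), n_pooled)
        ca = _csmfa_mv(ref_q.to_numpy(), out_q.to_numpy(), pooled_causes)
        results.append(
            EvalResult("overall", "all", name, len(rec), pccc=mv, csmf_accuracy=ca)
        )

        # age groups
        for s in strata_present:
            mask = (rec["stratum"] == s.value).to_numpy()
            r_arr, p_arr = reference.to_numpy()[mask], out.to_numpy()[mask]
            n_cats = len(cat_lists[s])
            if n_cats < 2:
                # metrics are undefined on a single-cause stratum
                results.append(
                    EvalResult("age_group", s.value, name, int(mask.sum()),
                               excluded=True, reason="single-cause stratum")
                )
                continue
            results.append(
                EvalResult(
                    "age_group", s.value, name, int(mask.sum()),
                    pccc=_pccc_mv(r_arr, p_arr, n_cats),
                    csmf_accuracy=_csmfa_mv(r_arr, p_arr, cat_lists[s]),
                )
            )

        # causes (restricted to the conditioning cause)
        cond = reference if config.condition_on == "reference" else out
        for s in strata_present:
            mask = (rec["stratum"] == s.value).to_numpy()
            r_arr, p_arr = reference.to_numpy()[mask], out.to_numpy()[mask]
            c_arr = cond.to_numpy()[mask]
            for cause in cat_lists[s]:
                sub = c_arr == cause
                n_c = int(sub.sum())
                key = f"{s.value}:{cause}"
                if n_c == 0:
                    results.append(
                        EvalResult("cause", key, name, 0, excluded=True,
                                   reason="no records")
                    )
                    continue
                mv_c = _pccc_mv(r_arr[sub], p_arr[sub], len(cat_lists[s]))
                results.append(EvalResult("cause", key, name, n_c, pccc=mv_c))

        # fine age bands (pooled label space within the band)
        band_labels = rec["age_days"].map(bands.band_of)
        for label in bands.labels:
            mask = (band_labels == label).to_numpy()
            n_b = int(mask.sum())
            if n_b == 0:
                continue
            strata_in_band = {
                AgeStratum(s) for s in rec["stratum"].to_numpy()[mask]
            }
            n_cats = sum(len(cat_lists[s]) for s in strata_in_band)
            mv_b = _pccc_mv(ref_q.to_numpy()[mask], out_q.to_numpy()[mask], n_cats)
            results.append(EvalResult("age_band", label, name, n_b, pccc=mv_b))

    return exclude_low_n(EvalResults(results, config), config.min_n)


def exclude_low_n(
    results: EvalResults, min_n: int, min_fraction: Optional[float] = None
) -> EvalResults:
    """Flag low-count cause strata as excluded.

    A cause stratum is excluded when its record count is below ``min_n`` or,
    if ``min_fraction`` is given, below that fraction of its age group's
    records.  Excluded results carry no metric values; all other strata are
    returned untouched.
    """
    group_n = {
        r.key: r.n for r in results.results if r.kind == "age_group"
    }
    out = []
    for r in results.results:
        if r.kind != "cause":
            out.append(r)
            continue
        stratum = r.key.split(":", 1)[0]
        low = r.n < min_n
        if min_fraction is not None and group_n.get(stratum):
            low = low or (r.n / group_n[stratum]) < min_fraction
        if low and not r.excluded:
            out.append(
                replace(r, pccc=None, csmf_accuracy=None, excluded=True,
                        reason=f"n={r.n} < min_n={min_n}")
            )
        else:
            out.append(r)
    return EvalResults(out, results.config)


def rank_and_range(
    results: Sequence[EvalResult],
) -> tuple[list[tuple[str, float]], float]:
    """Order coders by PCCC (descending, ties by name) within one stratum.

    Returns the ordered (coder, point) list and the range (max - min PCCC
    across coders).  Requires at least one non-excluded result.
    """
    keys = {(r.kind, r.key) for r in results}
    if len(keys) > 1:
        raise ContractError(f"rank_and_range expects one stratum, got {sorted(keys)}")
    usable = [r for r in results if not r.excluded and r.pccc is not None]
    if not usable:
        raise ContractError("no non-excluded results to rank")
    ordered = sorted(usable, key=lambda r: (-r.pccc.point, r.coder))
    points = [r.pccc.point for r in ordered]
    return [(r.coder, r.pccc.point) for r in ordered], points[0] - points[-1]
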