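"""Dual-physician coding workflow.

Every record is independently coded by two physicians.  Agreement is judged
at the CMEA-10 group level: the record is in agreement iff both ICD-10 codes
fall inside the same (non-missing) CMEA-10 group.  Disagreements enter a
reconciliation round (each physician may retain, adopt the other's code, or
assign a new one) and, if still unresolved, senior adjudication.  The
evaluation pipeline itself uses only records with *initial* agreement and a
valid CGHR-10 category; reconciliation and adjudication are provided as
simulations for synthetic cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .codes import AgeStratum, CmeaGroupTable, CodeMapTable, cmea_group_of
from .errors import ConfigurationError, ContractError

__all__ = [
    "CauseAssignment",
    "AgreementOutcome",
    "ReconciliationPolicy",
    "SeniorPolicy",
    "dual_agreement",
    "simulate_reconciliation",
    "simulate_adjudication",
    "filter_agreed_valid",
]


@dataclass
class CauseAssignment:
    """One coder's cause assignment for one record."""

    record_id: str
    coder_id: str
    code_system: str  # ICD10 | WHOVA2016 | CGHR10
    code: str
    phase: str = "initial"  # initial | reconciled | adjudicated
    cghr: Optional[str] = None  # CGHR-10 category id, or None when unmapped


@dataclass
class AgreementOutcome:
    """Result of comparing two physicians' initial assignments."""

    record_id: str
    agreed: bool
    group_a: Optional[str]
    group_b: Optional[str]
    resolution: str  # initial_agreement | reconciled | adjudicated | unresolved

    def __post_init__(self) -> None:
        if self.agreed and (self.group_a != self.group_b or self.group_a is None):
            raise ContractError(
                "agreed outcome requires both codes in the same non-missing CMEA group"
            )


def dual_agreement(
    a: CauseAssignment, b: CauseAssignment, cmea: CmeaGroupTable
) -> AgreementOutcome:
    """Judge initial agreement of two assignments via CMEA-10 groups.

    Agreement requires both codes to map to the same non-missing group; a
    code outside all groups never agrees (including with an identical code
    outside all groups).  Symmetric in its two assignments.
    """
    if a.record_id != b.record_id:
        raise ContractError(
            f"assignments refer to different records: {a.record_id!r} vs {b.record_id!r}"
        )
    for x in (a, b):
        if x.phase != "initial":
            raise ContractError(f"dual_agreement requires initial-phase assignments")
    ga = cmea_group_of(a.code, cmea)
    gb = cmea_group_of(b.code, cmea)
    agreed = ga is not None and ga == gb
    return AgreementOutcome(
        record_id=a.record_id,
        agreed=agreed,
        group_a=ga,
        group_b=gb,
        resolution="initial_agreement" if agreed else "unresolved",
    )


@dataclass
class ReconciliationPolicy:
    """Probabilities with which a physician retains, adopts, or re-codes."""

    retain: float = 0.5
    adopt: float = 0.3
    new: float = 0.2
    #: sampler for a fresh code, required when ``new > 0``
    new_code_sampler: Optional[Callable[[np.random.Generator], str]] = None

    def __post_init__(self) -> None:
        total = self.retain + self.adopt + self.new
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"reconciliation probabilities must sum to 1, got {total}"
            )
        if min(self.retain, self.adopt, self.new) < 0:
            raise ConfigurationError("reconciliation probabilities must be non-negative")
        if self.new > 0 and self.new_code_sampler is None:
            raise ConfigurationError("new_code_sampler required when new > 0")

    def draw(self, own_code: str, other_code: str, rng: np.random.Generator) -> str:
        action = rng.choice(("retain", "adopt", "new"), p=(self.retain, self.adopt, self.new))
        if action == "retain":
            return own_code
        if action == "adopt":
            return other_code
        return self.new_code_sampler(rng)


def simulate_reconciliation(
    outcome: AgreementOutcome,
    a: CauseAssignment,
    b: CauseAssignment,
    policy: ReconciliationPolicy,
    cmea: CmeaGroupTable,
    rng_seed: int | np.random.Generator = 0,
) -> tuple[AgreementOutcome, CauseAssignment, CauseAssignment]:
    """Simulate one reconciliation round for a disagreeing record.

    Each physician independently draws an action from ``policy``.  If the
    resulting codes fall in the same CMEA-10 group the record is reconciled,
    otherwise it stays unresolved (eligible for adjudication).
    """
    if outcome.agreed:
        raise ContractError("reconciliation applies only to disagreeing records")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    new_a = replace(a, code=policy.draw(a.code, b.code, rng), phase="reconciled")
    new_b = replace(b, code=policy.draw(b.code, a.code, rng), phase="reconciled")
    ga, gb = cmea_group_of(new_a.code, cmea), cmea_group_of(new_b.code, cmea)
    agreed = ga is not None and ga == gb
    new_outcome = AgreementOutcome(
        record_id=outcome.record_id,
        agreed=agreed,
        group_a=ga,
        group_b=gb,
        resolution="reconciled" if agreed else "unresolved",
    )
    return new_outcome, new_a, new_b


@dataclass
class SeniorPolicy:
    """How a senior physician resolves an unresolved record."""

    pick_a: float = 0.45
    pick_b: float = 0.45
    fresh: float = 0.10
    fresh_code_sampler: Optional[Callable[[np.random.Generator], str]] = None

    def __post_init__(self) -> None:
        total = self.pick_a + self.pick_b + self.fresh
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError("senior policy probabilities must sum to 1")
        if self.fresh > 0 and self.fresh_code_sampler is None:
            raise ConfigurationError("fresh_code_sampler required when fresh > 0")


def simulate_adjudication(
    outcome: AgreementOutcome,
    a: CauseAssignment,
    b: CauseAssignment,
    senior_policy: SeniorPolicy,
    rng_seed: int | np.random.Generator = 0,
) -> CauseAssignment:
    """Simulate senior adjudication: one final code is issued."""
    if outcome.resolution != "unresolved":
        raise ContractError("adjudication applies only to unresolved records")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    choice = rng.choice(
        ("a", "b", "fresh"),
        p=(senior_policy.pick_a, senior_policy.pick_b, senior_policy.fresh),
    )
    if choice == "a":
        code = a.code
    elif choice == "b":
        code = b.code
    else:
        code = senior_policy.fresh_code_sampler(rng)
    return CauseAssignment(
        record_id=outcome.record_id,
        coder_id="senior",
        code_system=a.code_system,
        code=code,
        phase="adjudicated",
    )


def filter_agreed_valid(
    records: pd.DataFrame,
    assignments: pd.DataFrame,
    cmea: CmeaGroupTable,
    code_map: CodeMapTable,
) -> tuple[pd.DataFrame, dict]:
    """Keep records with initial physician agreement and a valid CGHR-10 category.

    ``records`` must carry ``record_id``, ``stratum``; ``assignments`` must
    contain exactly two initial-phase physician assignments per record
    (``record_id, coder_id, code_system, code, phase``).  Returns the kept
    records (with a ``reference_cghr`` column holding the physician CGHR-10
    category) and an audit dict with counts at each filter step, overall and
    per stratum.
    """
    initial = assignments[assignments["phase"] == "initial"]
    counts = initial.groupby("record_id").size()
    known = set(records["record_id"])
    bad = sorted(
        set(counts.index[counts != 2]) | (known - set(counts.index))
    )
    if bad:
        raise ContractError(
            f"records without exactly two initial assignments: {bad[:20]}"
            + ("..." if len(bad) > 20 else "")
        )

    initial = initial[initial["record_id"].isin(known)].copy()
    group_of = {c: cmea.lookup(c) for c in initial["code"].unique()}
    initial["cmea_group"] = initial["code"].map(group_of)

    # pair up the two assignments per record (coder identity is irrelevant)
    initial["slot"] = initial.groupby("record_id").cumcount()
    wide = initial.pivot(index="record_id", columns="slot", values=["code", "cmea_group"])
    agreed = (
        wide[("cmea_group", 0)].notna()
        & (wide[("cmea_group", 0)] == wide[("cmea_group", 1)])
    )

    rec = records.set_index("record_id")
    stratum_of = rec["stratum"].map(lambda s: AgeStratum(s))
    ref_code = wide[("code", 0)]

    _map_cache: dict[tuple, Optional[str]] = {}

    def _map(record_id: str) -> Optional[str]:
        key = (ref_code.loc[record_id], stratum_of.loc[record_id])
        if key not in _map_cache:
            _map_cache[key] = code_map.lookup(key[0], key[1], "ICD10")
        return _map_cache[key]

    reference = pd.Series(
        {rid: _map(rid) for rid in wide.index[agreed]}, dtype=object
    )
    valid = reference.dropna()

    def _per_stratum(ids) -> dict[str, int]:
        out = {s.value: 0 for s in AgeStratum}
        vc = stratum_of.loc[list(ids)].value_counts()
        for k, v in vc.items():
            out[AgeStratum(k).value] = int(v)
        return out

    audit = {
        "total": int(len(records)),
        "agreed": int(agreed.sum()),
        "agreed_valid": int(len(valid)),
        "by_stratum": {
            "total": _per_stratum(records["record_id"]),
            "agreed": _per_stratum(wide.index[agreed]),
            "agreed_valid": _per_stratum(valid.index),
        },
    }

    kept = records[records["record_id"].isin(valid.index)].copy()
    kept["reference_cghr"] = kept["record_id"].map(valid)
    return kept, audit
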