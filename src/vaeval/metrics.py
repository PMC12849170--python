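"""Agreement metrics for cause-of-death assignment.

Individual level — partial chance-corrected concordance (PCCC).  With a
single assigned cause per record (the k = 1 case; every coder here emits one
cause of death), the concordance fraction C is the share of records whose
assigned category equals the reference, and

    PCCC = (C - 1/N) / (1 - 1/N)

where N is the number of categories in the stratum's cause list.  Chance
level scores 0 and perfect agreement scores 1.  Negative raw values are
clamped to 0 for reporting; the raw value is retained.

Population level — CSMF accuracy.  With cause-specific mortality fractions
(CSMFs) over a common cause list,

    CSMFA = 1 - sum_j |pred_j - ref_j| / (2 (1 - min_j ref_j)),

i.e. 1 minus total absolute error normalized by the maximum error attainable
(a predictor putting all mass on the rarest reference cause scores exactly 0).

Uncertainty — percentile bootstrap over records (the resampling unit is the
(reference, predicted) pair), 1000 resamples with replacement by default for
a 95% interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import ConfigurationError, ContractError, UndefinedStratumError

__all__ = [
    "MetricValue",
    "ConcordanceInput",
    "concordance_fraction",
    "pccc_point",
    "pccc",
    "csmf",
    "csmf_accuracy",
    "bootstrap_ci",
]


@dataclass
class MetricValue:
    """A metric point estimate with its bootstrap interval.

    ``raw`` is the pre-clamping value (PCCC only); ``point`` is clamped to
    [0, 1].  ``ci_low``/``ci_high`` are NaN when no bootstrap was run.
    """

    point: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n: int = 0
    raw: Optional[float] = None


@dataclass
class ConcordanceInput:
    """Paired reference (physician) and predicted (coder) category ids."""

    reference: np.ndarray
    predicted: np.ndarray
    n_categories: int

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=object)
        self.predicted = np.asarray(self.predicted, dtype=object)
        if self.reference.shape != self.predicted.shape:
            raise ContractError("reference and predicted must have equal length")
        if self.n_categories < 2:
            raise ConfigurationError("need at least two categories (N >= 2)")


def _restrict(reference, predicted, cause):
    ref = np.asarray(reference, dtype=object)
    pred = np.asarray(predicted, dtype=object)
    if ref.shape != pred.shape:
        raise ContractError("reference and predicted must have equal length")
    if cause is not None:
        mask = ref == cause
        ref, pred = ref[mask], pred[mask]
    if ref.size == 0:
        raise UndefinedStratumError(
            "empty restriction"
            + (f" for cause {cause!r}" if cause is not None else "")
        )
    return ref, pred


def concordance_fraction(reference, predicted, cause: Optional[str] = None) -> float:
    """Fraction of records with predicted = reference.

    With ``cause`` given, restrict to records whose *reference* equals that
    cause first; an empty restriction raises :class:`UndefinedStratumError`
    (callers exclude such strata).
    """
    ref, pred = _restrict(reference, predicted, cause)
    return float(np.mean(ref == pred))


def pccc_point(c: float, n_categories: int) -> tuple[float, float]:
    """(raw, clamped) chance-corrected concordance for concordance ``c``."""
    if n_categories < 2:
        raise ConfigurationError("PCCC requires at least two categories")
    raw = (c - 1.0 / n_categories) / (1.0 - 1.0 / n_categories)
    return raw, min(1.0, max(0.0, raw))


def pccc(
    reference,
    predicted,
    n_categories: int,
    cause: Optional[str] = None,
    bootstrap_B: Optional[int] = None,
    level: float = 0.95,
    rng=None,
) -> MetricValue:
    """Chance-corrected concordance with an optional percentile bootstrap CI.

    The bootstrap resamples the (reference, predicted) pairs of the (cause-
    restricted) input and recomputes the clamped PCCC on each resample.
    """
    ref, pred = _restrict(reference, predicted, cause)
    c = float(np.mean(ref == pred))
    raw, point = pccc_point(c, n_categories)
    mv = MetricValue(point=point, raw=raw, n=int(ref.size))
    if bootstrap_B:
        lo, hi = bootstrap_ci(
            lambda r, p: pccc_point(float(np.mean(r == p)), n_categories)[1],
            (ref, pred),
            B=bootstrap_B,
            level=level,
            rng=rng,
        )
        mv.ci_low, mv.ci_high = lo, hi
    return mv


def csmf(assignments, causes: Sequence[str]) -> np.ndarray:
    """Cause-specific mortality fractions over the full cause list.

    Unobserved causes get fraction 0; the result sums to 1.  An assignment
    outside the cause list is a contract error.
    """
    arr = np.asarray(assignments, dtype=object)
    if arr.size == 0:
        raise ContractError("csmf requires at least one assignment")
    index = {c: i for i, c in enumerate(causes)}
    counts = np.zeros(len(causes))
    for a in arr:
        if a not in index:
            raise ContractError(f"assignment {a!r} outside the cause list")
        counts[index[a]] += 1
    return counts / counts.sum()


def csmf_accuracy(pred_csmf, ref_csmf) -> float:
    """CSMF accuracy of a predicted fraction vector against a reference.

    Both vectors must cover the same cause list and sum to 1; a reference
    concentrated on a single cause makes the normalizer degenerate and is a
    configuration error.  The result is clamped to [0, 1] against floating
    point drift.
    """
    pred = np.asarray(pred_csmf, dtype=float)
    ref = np.asarray(ref_csmf, dtype=float)
    if pred.shape != ref.shape:
        raise ContractError("CSMF vectors must cover the same cause list")
    if ref.size < 2:
        raise ConfigurationError("CSMF accuracy requires at least two causes")
    for name, v in (("pred", pred), ("ref", ref)):
        if abs(v.sum() - 1.0) > 1e-6:
            raise ConfigurationError(f"{name} CSMF vector must sum to 1")
    if float(ref.max()) >= 1.0 - 1e-12:
        raise ConfigurationError("degenerate single-cause reference CSMF")
    ref_min = float(ref.min())
    acc = 1.0 - np.abs(pred - ref).sum() / (2.0 * (1.0 - ref_min))
    return min(1.0, max(0.0, float(acc)))


def bootstrap_ci(
    metric_fn: Callable[..., float],
    data: Sequence,
    B: int = 1000,
    level: float = 0.95,
    rng=None,
    max_retries: int = 100,
) -> tuple[float, float]:
    """Percentile bootstrap interval for a metric of paired record data.

    ``data`` is a tuple of equal-length arrays resampled jointly with
    replacement (the record is the resampling unit).  If the metric is
    undefined on a resample (raises a vaeval error, e.g. a cause absent from
    the resample) the resample is redrawn, up to ``max_retries`` times before
    giving up.
    """
    from .errors import VaevalError

    arrays = [np.asarray(a) for a in data]
    if not arrays:
        raise ContractError("bootstrap requires data")
    n = arrays[0].shape[0]
    if n == 0:
        raise ContractError("bootstrap requires non-empty data")
    if any(a.shape[0] != n for a in arrays):
        raise ContractError("bootstrap data arrays must have equal length")
    if B < 1:
        raise ConfigurationError("B must be >= 1")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    stats = np.empty(B)
    for b in range(B):
        for _ in range(max_retries):
            idx = gen.integers(0, n, n)
            try:
                stats[b] = metric_fn(*(a[idx] for a in arrays))
                break
            except VaevalError:
                continue
        else:
            raise ConfigurationError(
                f"metric undefined on {max_retries} consecutive bootstrap resamples"
            )
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
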