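"""Automated cause-of-death coders behind one adapter contract.

Three coders are provided:

* :class:`BayesCoder` — a naive-Bayes maximum-probability coder in the style
  of symptom-driven VA algorithms: cause priors and per-cause symptom
  conditional probabilities (a "probbase") combine with a record's binary
  symptom vector into a posterior over causes; the argmax cause is assigned.
* :func:`build_prompt` — the narrative prompt template used to query large
  language models for an ICD-10 cause; no API call is made here, the adapter
  contract lets users plug a real client.
* :class:`SimulatedCoder` — a confusion-matrix-driven stand-in for external
  coders (LLMs, MCMC-based models): given a record's true cause it draws the
  assigned cause from that cause's confusion row.

All coders implement ``assign(record) -> CauseAssignment`` and are
deterministic for a fixed seed and inputs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .codes import AgeStratum
from .errors import ConfigurationError, ValidationError
from .workflow import CauseAssignment

__all__ = [
    "Probbase",
    "ConfusionSpec",
    "BayesCoder",
    "SimulatedCoder",
    "bayes_posterior",
    "bayes_assign",
    "build_prompt",
    "parse_prompt",
    "PROMPT_TEMPLATE",
    "INDETERMINATE",
    "identity_confusion",
    "uniform_confusion",
    "diagonal_confusion",
]

INDETERMINATE = "indeterminate"


@dataclass
class Probbase:
    """Cause priors and per-cause symptom conditional probabilities.

    ``cond[j, i]`` is P(symptom i present | cause j); all entries must lie
    strictly inside (0, 1) so no single symptom can zero out a cause.
    """

    causes: list[str]
    symptoms: list[str]
    priors: np.ndarray  # shape (n_causes,)
    cond: np.ndarray  # shape (n_causes, n_symptoms)

    def __post_init__(self) -> None:
        self.priors = np.asarray(self.priors, dtype=float)
        self.cond = np.asarray(self.cond, dtype=float)
        if self.cond.shape != (len(self.causes), len(self.symptoms)):
            raise ConfigurationError(
                f"probbase shape {self.cond.shape} inconsistent with "
                f"{len(self.causes)} causes x {len(self.symptoms)} symptoms"
            )
        if abs(self.priors.sum() - 1.0) > 1e-9:
            raise ConfigurationError("probbase priors must sum to 1")
        if np.any(self.priors < 0):
            raise ConfigurationError("probbase priors must be non-negative")
        if np.any(self.cond <= 0.0) or np.any(self.cond >= 1.0):
            raise ConfigurationError(
                "probbase conditional probabilities must be strictly inside (0, 1)"
            )

    @classmethod
    def from_csv(cls, path) -> "Probbase":
        """Read a probbase CSV: first column ``cause``, column ``prior``,
        then one column per symptom id."""
        df = pd.read_csv(path)
        if df.columns[0] != "cause" or "prior" not in df.columns:
            raise ConfigurationError(f"malformed probbase CSV: {path}")
        symptoms = [c for c in df.columns if c not in ("cause", "prior")]
        priors = df["prior"].to_numpy(dtype=float)
        return cls(
            causes=df["cause"].tolist(),
            symptoms=symptoms,
            priors=priors / priors.sum(),  # undo CSV rounding drift
            cond=df[symptoms].to_numpy(),
        )

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.cond, columns=self.symptoms)
        df.insert(0, "prior", self.priors)
        df.insert(0, "cause", self.causes)
        df.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")


def bayes_posterior(
    symptoms, pb: Probbase, absence_mode: str = "complement"
) -> np.ndarray:
    """Posterior over causes given a binary symptom vector.

    ``symptoms`` entries are 1 (present), 0 (absent), or NaN (missing).
    Present symptoms contribute ``cond``; absent symptoms contribute the
    ``1 - cond`` complement when ``absence_mode="complement"`` (full naive
    Bayes) and are skipped when ``absence_mode="ignore"`` (the dialect of
    some questionnaire-driven coders).  Missing symptoms never contribute,
    so an all-missing vector returns the priors.  Computation is in log
    space; the result is normalized to sum to 1.
    """
    if absence_mode not in ("complement", "ignore"):
        raise ConfigurationError(f"unknown absence_mode: {absence_mode!r}")
    s = np.asarray(symptoms, dtype=float)
    if s.shape != (len(pb.symptoms),):
        raise ConfigurationError(
            f"symptom vector length {s.shape} does not match probbase "
            f"({len(pb.symptoms)} symptoms)"
        )
    bad = s[~np.isnan(s)]
    if not np.all(np.isin(bad, (0.0, 1.0))):
        raise ValidationError("symptom entries must be 0, 1 or missing (NaN)")

    log_post = np.log(pb.priors.clip(min=1e-300)).copy()
    present = s == 1.0
    absent = s == 0.0
    log_post += np.log(pb.cond[:, present]).sum(axis=1)
    if absence_mode == "complement":
        log_post += np.log1p(-pb.cond[:, absent]).sum(axis=1)
    log_post -= log_post.max()
    post = np.exp(log_post)
    return post / post.sum()


def bayes_assign(
    posterior, causes: Sequence[str], indeterminate_threshold: float = 0.0
) -> str:
    """Argmax cause if its posterior clears the threshold, else indeterminate.

    Exact ties are broken by position in ``causes`` (first wins), a fixed,
    documented order.
    """
    post = np.asarray(posterior, dtype=float)
    if abs(post.sum() - 1.0) > 1e-6:
        raise ConfigurationError("posterior must sum to 1")
    j = int(np.argmax(post))
    if post[j] >= indeterminate_threshold:
        return causes[j]
    return INDETERMINATE


# --------------------------------------------------------------------------
# LLM prompt template
# --------------------------------------------------------------------------

PROMPT_TEMPLATE = (
    "Determine the underlying cause of death and provide the most probable "
    "ICD-10 code for a verbal autopsy narrative of a {age} years old {sex} "
    "death in Sierra Leone: {narrative}"
)

_PROMPT_RE = re.compile(
    r"^Determine the underlying cause of death and provide the most probable "
    r"ICD-10 code for a verbal autopsy narrative of a (?P<age>\S+) years old "
    r"(?P<sex>\S+) death in Sierra Leone: (?P<narrative>.*)$",
    re.DOTALL,
)


def build_prompt(age_years, sex: str, narrative: str) -> str:
    """Fill the narrative prompt template for an LLM coder.

    The output is byte-identical to :data:`PROMPT_TEMPLATE` apart from the
    three substituted placeholders.  An empty narrative raises
    :class:`ValidationError`.
    """
    if narrative is None or not str(narrative).strip():
        raise ValidationError("narrative must be non-empty")
    return PROMPT_TEMPLATE.format(age=age_years, sex=sex, narrative=narrative)


def parse_prompt(prompt: str) -> tuple[str, str, str]:
    """Invert :func:`build_prompt`, recovering (age, sex, narrative)."""
    m = _PROMPT_RE.match(prompt)
    if not m:
        raise ValidationError("text does not match the prompt template")
    return m.group("age"), m.group("sex"), m.group("narrative")


# --------------------------------------------------------------------------
# Confusion-driven simulated coder
# --------------------------------------------------------------------------


class ConfusionSpec:
    """Per-stratum confusion matrices P(assigned = k | true = j).

    Each stratum's matrix is a square DataFrame over that stratum's category
    set, rows indexed by true cause, columns by assigned cause, each row
    summing to 1.
    """

    def __init__(self, matrices: Mapping[AgeStratum | str, pd.DataFrame]):
        self.matrices: dict[AgeStratum, pd.DataFrame] = {}
        for stratum, m in matrices.items():
            stratum = AgeStratum(stratum)
            m = m.astype(float)
            if list(m.index) != list(m.columns):
                raise ConfigurationError(
                    f"confusion matrix for {stratum.value} is not square on one category set"
                )
            if np.any(m.to_numpy() < 0):
                raise ConfigurationError("confusion probabilities must be non-negative")
            if not np.allclose(m.sum(axis=1).to_numpy(), 1.0, atol=1e-9):
                raise ConfigurationError(
                    f"confusion rows for {stratum.value} must each sum to 1"
                )
            self.matrices[stratum] = m

    def row(self, stratum: AgeStratum | str, true_cause: str) -> pd.Series:
        m = self.matrices[AgeStratum(stratum)]
        if true_cause not in m.index:
            raise ConfigurationError(
                f"true cause {true_cause!r} not in the confusion spec for "
                f"{AgeStratum(stratum).value}"
            )
        return m.loc[true_cause]


def identity_confusion(causes: Sequence[str]) -> pd.DataFrame:
    """A perfect coder: assigned always equals true."""
    return pd.DataFrame(np.eye(len(causes)), index=list(causes), columns=list(causes))


def uniform_confusion(causes: Sequence[str]) -> pd.DataFrame:
    """A chance-level coder: assigned uniform over all causes."""
    n = len(causes)
    return pd.DataFrame(np.full((n, n), 1.0 / n), index=list(causes), columns=list(causes))


def diagonal_confusion(causes: Sequence[str], c: float) -> pd.DataFrame:
    """Probability ``c`` on the true cause, remainder uniform off-diagonal."""
    n = len(causes)
    if not 0.0 <= c <= 1.0:
        raise ConfigurationError("diagonal probability must lie in [0, 1]")
    if n < 2:
        raise ConfigurationError("need at least two causes")
    off = (1.0 - c) / (n - 1)
    m = np.full((n, n), off)
    np.fill_diagonal(m, c)
    return pd.DataFrame(m, index=list(causes), columns=list(causes))


@dataclass
class BayesCoder:
    """Naive-Bayes maximum-probability coder over per-stratum probbases.

    Indeterminate outputs (below-threshold posteriors) are mapped to the
    stratum's ill-defined category when ``indeterminate_category`` is set,
    so every record receives a scoreable category; the default threshold of
    0 always assigns the argmax cause.
    """

    probbases: Mapping[AgeStratum | str, Probbase]
    name: str = "bayes"
    code_system: str = "CGHR10"
    absence_mode: str = "complement"
    indeterminate_threshold: float = 0.0
    indeterminate_category: Optional[str] = "ill_defined"

    def __post_init__(self) -> None:
        self.probbases = {AgeStratum(s): pb for s, pb in self.probbases.items()}

    def posterior(self, record: Mapping) -> np.ndarray:
        pb = self.probbases[AgeStratum(record["stratum"])]
        s = np.array([float(record[sym]) for sym in pb.symptoms])
        return bayes_posterior(s, pb, absence_mode=self.absence_mode)

    def assign(self, record: Mapping) -> CauseAssignment:
        stratum = AgeStratum(record["stratum"])
        pb = self.probbases[stratum]
        cat = bayes_assign(
            self.posterior(record), pb.causes, self.indeterminate_threshold
        )
        if cat == INDETERMINATE and self.indeterminate_category is not None:
            cat = self.indeterminate_category
        return CauseAssignment(
            record_id=record["record_id"],
            coder_id=self.name,
            code_system=self.code_system,
            code=cat,
            phase="initial",
            cghr=cat,
        )


class SimulatedCoder:
    """Confusion-matrix stand-in for an external coder.

    For each record the assigned category is drawn from the confusion row of
    the record's true cause; requires a synthetic cohort (records must carry
    ``true_cause``).  Draws are reproducible for a fixed seed and record
    order.
    """

    code_system = "CGHR10"

    def __init__(self, spec: ConfusionSpec, name: str = "sim", seed: int | None = 0):
        self.spec = spec
        self.name = name
        self.rng = np.random.default_rng(seed)

    def assign(self, record: Mapping) -> CauseAssignment:
        true_cause = record.get("true_cause")
        if true_cause is None:
            raise ConfigurationError(
                "simulated coder requires records with a true cause (synthetic cohort)"
            )
        row = self.spec.row(record["stratum"], true_cause)
        cat = self.rng.choice(row.index.to_numpy(), p=row.to_numpy())
        return CauseAssignment(
            record_id=record["record_id"],
            coder_id=self.name,
            code_system=self.code_system,
            code=str(cat),
            phase="initial",
            cghr=str(cat),
        )
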