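"""Synthetic verbal-autopsy cohorts.

Generates cohorts with the statistical structure the evaluation pipeline
assumes — per-stratum sizes, cause distributions, symptom vectors emitted
from a probbase, template narratives, dual-physician ICD-10 codes with
per-cause agreement rates, and coder outputs with specified confusion — so
every pipeline stage is testable without any external data.

What is emulated: the cohort *structure* (three age strata, CMEA-level
physician agreement, a handful of records whose agreed code falls outside
the CGHR-10 map).  What is not: realistic clinical narrative prose, WHO-2016
questionnaire structure, or demographic realism of the age distribution
(ages are uniform within stratum bounds).

The published-shape spec (:func:`published_cohort_spec`) reproduces the published
filter chain exactly: 11,920 initial records, 6,942 with initial physician
agreement, and 6,939 agreed records with a valid CGHR-10 category
(3,826 adult / 2,636 child / 477 neonatal).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .coders import ConfusionSpec, Probbase, SimulatedCoder
from .codes import (
    ADULT_UPPER_DAYS,
    CHILD_UPPER_DAYS,
    NEONATE_UPPER_DAYS,
    AgeStratum,
    CmeaGroupTable,
    CodeMapTable,
    enumerate_codes,
)
from .errors import ConfigurationError
from .resources import default_categories, default_cmea_table, default_code_map

__all__ = [
    "SYMPTOM_NAMES",
    "CohortSpec",
    "FixtureBundle",
    "make_synthetic_probbase",
    "default_cohort_spec",
    "published_cohort_spec",
    "generate_cohort",
    "generate_coder_outputs",
    "write_fixture_bundle",
    "read_fixture_bundle",
]

#: default symptom indicator columns (binary; 1 = reported present)
SYMPTOM_NAMES = [
    "fever", "cough", "breathless", "chest_pain", "loose_stools",
    "vomiting", "abdominal_pain", "headache", "stiff_neck", "rash",
    "weight_loss", "night_sweats", "swelling", "jaundice", "convulsions",
    "unconscious", "pallor", "injury_event", "pregnancy_related",
    "birth_complication",
]

_STRATUM_AGE_BOUNDS = {
    AgeStratum.NEONATE: (0, NEONATE_UPPER_DAYS),
    AgeStratum.CHILD: (NEONATE_UPPER_DAYS, CHILD_UPPER_DAYS),
    AgeStratum.ADULT: (CHILD_UPPER_DAYS, ADULT_UPPER_DAYS),
}

_STRATUM_PREFIX = {AgeStratum.ADULT: "A", AgeStratum.CHILD: "C", AgeStratum.NEONATE: "N"}

#: codes used for agreed-but-unmappable records; inside a CMEA-10 group
#: (so both physicians agree) but outside every CGHR-10 map range
UNMAPPABLE_CODES = [f"U{d}" for d in range(60, 70)]


def make_synthetic_probbase(
    causes: Sequence[str],
    symptoms: Optional[Sequence[str]] = None,
    seed: int = 0,
    n_signature: int = 3,
) -> Probbase:
    """Generate a synthetic probbase: each cause gets a few high-probability
    "signature" symptoms against a low base rate.

    Purely synthetic — no claim of fidelity to any published expert table.
    """
    symptoms = list(symptoms if symptoms is not None else SYMPTOM_NAMES)
    rng = np.random.default_rng(seed)
    n_c, n_s = len(causes), len(symptoms)
    cond = rng.uniform(0.02, 0.15, size=(n_c, n_s))
    for j in range(n_c):
        sig = rng.choice(n_s, size=min(n_signature, n_s), replace=False)
        cond[j, sig] = rng.uniform(0.6, 0.9, size=len(sig))
    priors = rng.dirichlet(np.full(n_c, 2.0))
    return Probbase(causes=list(causes), symptoms=symptoms, priors=priors, cond=cond)


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    ``agreement_rate`` may be a single float or a per-stratum mapping of
    per-cause probabilities that both physicians initially agree.  When
    ``agreed_counts`` is set, exactly that many records per stratum agree
    (a uniform random subset; used to reproduce exact published counts),
    overriding the stochastic per-cause rates.  ``n_unmappable`` agreed
    records in ``unmappable_stratum`` receive an identical out-of-map code.
    """

    stratum_sizes: dict[str, int]
    cause_dist: dict[str, dict[str, float]]
    agreement_rate: Union[float, dict[str, dict[str, float]]] = 0.55
    disagreement_kernel: Optional[dict[str, dict[str, dict[str, float]]]] = None
    agreed_counts: Optional[dict[str, int]] = None
    n_unmappable: int = 0
    unmappable_stratum: str = "adult"
    n_symptoms: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for s, n in self.stratum_sizes.items():
            AgeStratum(s)
            if n < 0:
                raise ConfigurationError(f"negative stratum size for {s}")
        for s, dist in self.cause_dist.items():
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-6:
                raise ConfigurationError(
                    f"cause distribution for {s} sums to {total}, expected 1"
                )
            if any(p < 0 for p in dist.values()):
                raise ConfigurationError("cause probabilities must be non-negative")
        if isinstance(self.agreement_rate, (int, float)):
            if not 0.0 <= float(self.agreement_rate) <= 1.0:
                raise ConfigurationError("agreement_rate must lie in [0, 1]")
        else:
            for s, rates in self.agreement_rate.items():
                for c, r in rates.items():
                    if not 0.0 <= r <= 1.0:
                        raise ConfigurationError(
                            f"agreement rate for ({s}, {c}) must lie in [0, 1]"
                        )
        if self.n_unmappable < 0:
            raise ConfigurationError("n_unmappable must be >= 0")

    def rate_for(self, stratum: str, cause: str) -> float:
        if isinstance(self.agreement_rate, (int, float)):
            return float(self.agreement_rate)
        return float(self.agreement_rate.get(stratum, {}).get(cause, 0.55))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSpec":
        return cls(**{k: d[k] for k in d if k in {f.name for f in dataclasses.fields(cls)}})


# Illustrative per-cause initial-agreement rates; the quoted per-cause values
# (malaria 0.77 adult / 0.85 child, pneumonia 0.34/0.31, cancers 0.20,
# road/other injuries 0.75/0.72, child injuries 0.76, nutritional 0.39,
# unspecified infections 0.37, stillbirth 0.76) anchor the published range
# of roughly 20%-85%; unquoted causes sit at 0.5-0.6.
_DEFAULT_AGREEMENT = {
    "adult": {
        "malaria": 0.77, "pneumonia": 0.34, "cancers": 0.20,
        "other_infections": 0.37, "road_transport": 0.75,
        "other_injuries": 0.72, "maternal": 0.60, "tuberculosis": 0.55,
        "stroke": 0.55, "ischemic_heart": 0.55, "diarrhoeal": 0.55,
        "chronic_respiratory": 0.50, "diabetes": 0.55, "liver_alcohol": 0.50,
        "other_ncd": 0.45, "anaemia_nutritional": 0.50, "ill_defined": 0.40,
        "suicide": 0.60, "homicide": 0.60,
    },
    "child": {
        "malaria": 0.85, "pneumonia": 0.31, "diarrhoeal": 0.60,
        "other_infections": 0.45, "nutritional": 0.39, "injuries": 0.76,
        "other_ncd": 0.45, "epilepsy": 0.55, "congenital": 0.55,
        "ill_defined": 0.40,
    },
    "neonate": {
        "stillbirth": 0.76, "prematurity_lbw": 0.60,
        "birth_asphyxia_trauma": 0.55, "neonatal_infections": 0.50,
        "congenital": 0.55, "ill_defined": 0.40, "other_neonatal": 0.45,
    },
}

# Illustrative cause mixes consistent with the published low-n exclusions
# (suicide ~3 adult records of 3,826; congenital 1-2; neonatal "other" ~5).
_ADULT_DIST = {
    "malaria": 0.16, "other_infections": 0.14, "ischemic_heart": 0.10,
    "stroke": 0.07, "diarrhoeal": 0.05, "pneumonia": 0.05,
    "tuberculosis": 0.05, "cancers": 0.05, "chronic_respiratory": 0.04,
    "diabetes": 0.03, "liver_alcohol": 0.03, "maternal": 0.05,
    "ill_defined": 0.08, "road_transport": 0.04, "other_injuries": 0.04,
    "anaemia_nutritional": 0.02, "other_ncd": 0.0492, "suicide": 0.0008,
    "homicide": 0.0,
}
_CHILD_DIST = {
    "malaria": 0.30, "pneumonia": 0.15, "diarrhoeal": 0.12,
    "other_infections": 0.15, "nutritional": 0.06, "ill_defined": 0.07,
    "injuries": 0.05, "epilepsy": 0.02, "congenital": 0.0004,
    "other_ncd": 0.0996,
}
_NEONATE_DIST = {
    "prematurity_lbw": 0.26, "birth_asphyxia_trauma": 0.25,
    "neonatal_infections": 0.22, "stillbirth": 0.17, "ill_defined": 0.0853,
    "congenital": 0.0042, "other_neonatal": 0.0105,
}


def _normalized(dist: dict[str, float]) -> dict[str, float]:
    total = sum(dist.values())
    return {k: v / total for k, v in dist.items()}


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """A small cohort (730 deaths) for demos and fast tests."""
    return CohortSpec(
        stratum_sizes={"adult": 400, "child": 250, "neonate": 80},
        cause_dist={
            "adult": _normalized(_ADULT_DIST),
            "child": _normalized(_CHILD_DIST),
            "neonate": _normalized(_NEONATE_DIST),
        },
        agreement_rate=_DEFAULT_AGREEMENT,
        seed=seed,
    )


def published_cohort_spec(seed: int = 0) -> CohortSpec:
    """The published cohort structure: 11,920 initial records filtering to
    6,942 agreed and 6,939 agreed-and-valid (3,826 / 2,636 / 477).

    The per-stratum split of the disagreeing records is not published; the
    extra records are allocated roughly proportionally.
    """
    return CohortSpec(
        stratum_sizes={"adult": 6629, "child": 4436, "neonate": 855},
        cause_dist={
            "adult": _normalized(_ADULT_DIST),
            "child": _normalized(_CHILD_DIST),
            "neonate": _normalized(_NEONATE_DIST),
        },
        agreement_rate=_DEFAULT_AGREEMENT,
        agreed_counts={"adult": 3829, "child": 2636, "neonate": 477},
        n_unmappable=3,
        unmappable_stratum="adult",
        seed=seed,
    )


@dataclass
class FixtureBundle:
    """Everything generate_cohort produces, plus the tables it used."""

    records: pd.DataFrame
    assignments: pd.DataFrame
    truth: pd.DataFrame
    spec: CohortSpec
    categories: dict
    code_map: CodeMapTable
    cmea: CmeaGroupTable
    probbases: dict[AgeStratum, Probbase]


def _age_phrase(age_days: int) -> str:
    if age_days < NEONATE_UPPER_DAYS:
        return f"{age_days} day old"
    if age_days < 365.25:
        return f"{int(age_days // 30.44)} month old"
    return f"{int(age_days // 365.25)} year old"


def _build_vocab(categories) -> dict[str, list[str]]:
    stop = {"and", "other", "of", "the", "causes", "diseases", "conditions"}
    vocab: dict[str, list[str]] = {}
    for cats in categories.values():
        for c in cats:
            words = [w.strip(",-").lower() for w in c.label.split()]
            toks = [w for w in words if w not in stop and len(w) > 2]
            vocab.setdefault(c.id, list(dict.fromkeys(toks)) or [c.id])
    return vocab


def _code_pools(code_map: CodeMapTable, cmea: CmeaGroupTable, categories):
    """Per (stratum, cause): list of candidate ICD-10 codes and their CMEA
    groups; per group: the codes available for the same-group second draw."""
    pools: dict[tuple, list[tuple[str, str]]] = {}
    group_codes: dict[str, list[str]] = {}
    for stratum, cats in categories.items():
        for cat in cats:
            ranges = code_map.ranges_for(stratum, cat.id, "ICD10")
            if not ranges:
                raise ConfigurationError(
                    f"cause {cat.id!r} ({stratum.value}) has no ICD-10 range configured"
                )
            entries = []
            for start, end in ranges:
                for code in enumerate_codes(start, end):
                    g = cmea.lookup(code)
                    if g is not None:
                        entries.append((code, g))
            if not entries:
                raise ConfigurationError(
                    f"cause {cat.id!r} ({stratum.value}) has no codes inside any CMEA group"
                )
            pools[(stratum, cat.id)] = entries
    for gid in cmea.group_ids:
        codes: list[str] = []
        for start, end in cmea.ranges_of(gid):
            codes.extend(enumerate_codes(start, end))
        group_codes[gid] = codes
    return pools, group_codes


def generate_cohort(
    spec: CohortSpec,
    categories=None,
    code_map: Optional[CodeMapTable] = None,
    cmea: Optional[CmeaGroupTable] = None,
    probbases: Optional[Mapping] = None,
) -> FixtureBundle:
    """Generate a synthetic dual-coded cohort from a spec.

    Per record: stratum -> age uniform within stratum bounds -> true cause
    from the stratum's cause distribution -> symptoms Bernoulli from the
    probbase row -> template narrative -> physician A's ICD-10 code drawn
    from the true cause's configured ranges; with the per-cause agreement
    probability physician B's code falls in the same CMEA-10 group, else it
    is drawn from another cause via the disagreement kernel.  Exactly
    ``spec.n_unmappable`` agreed records receive an identical out-of-map
    code.  Fully reproducible under ``spec.seed``.
    """
    categories = categories or default_categories()
    code_map = code_map or default_code_map()
    cmea = cmea or default_cmea_table()
    rng = np.random.default_rng(spec.seed)

    if probbases is None:
        pb_seeds = np.random.SeedSequence(spec.seed).spawn(3)
        probbases = {
            s: make_synthetic_probbase(
                [c.id for c in categories[s]],
                SYMPTOM_NAMES[: spec.n_symptoms],
                seed=sq,
            )
            for s, sq in zip(
                (AgeStratum.ADULT, AgeStratum.CHILD, AgeStratum.NEONATE), pb_seeds
            )
        }
    probbases = {AgeStratum(s): pb for s, pb in probbases.items()}

    pools, group_codes = _code_pools(code_map, cmea, categories)
    vocab = _build_vocab(categories)

    rec_rows, asg_rows, truth_rows = [], [], []
    for stratum in (AgeStratum.ADULT, AgeStratum.CHILD, AgeStratum.NEONATE):
        n = int(spec.stratum_sizes.get(stratum.value, 0))
        if n == 0:
            continue
        dist = spec.cause_dist.get(stratum.value)
        if not dist:
            raise ConfigurationError(f"no cause distribution for stratum {stratum.value}")
        cause_ids = list(dist)
        known = {c.id for c in categories[stratum]}
        unknown = set(cause_ids) - known
        if unknown:
            raise ConfigurationError(
                f"causes {sorted(unknown)} not in the {stratum.value} category list"
            )
        probs = np.array([dist[c] for c in cause_ids])
        lo, hi = _STRATUM_AGE_BOUNDS[stratum]
        pb = probbases[stratum]

        ages = rng.integers(lo, hi, size=n)
        sexes = rng.choice(["female", "male"], size=n)
        causes = rng.choice(cause_ids, size=n, p=probs)
        cause_idx = np.array([pb.causes.index(c) for c in causes])
        symptoms = (rng.random((n, len(pb.symptoms))) < pb.cond[cause_idx]).astype(int)

        # which records agree (exact count override or per-cause Bernoulli)
        if spec.agreed_counts is not None:
            k = int(spec.agreed_counts.get(stratum.value, 0))
            if k > n:
                raise ConfigurationError(
                    f"agreed_counts[{stratum.value}]={k} exceeds stratum size {n}"
                )
            agreed = np.zeros(n, dtype=bool)
            agreed[rng.permutation(n)[:k]] = True
        else:
            rates = np.array([spec.rate_for(stratum.value, c) for c in causes])
            agreed = rng.random(n) < rates

        # agreed records that will carry an out-of-map code
        unmappable = np.zeros(n, dtype=bool)
        if spec.n_unmappable and stratum.value == spec.unmappable_stratum:
            agreed_idx = np.flatnonzero(agreed)
            if len(agreed_idx) < spec.n_unmappable:
                raise ConfigurationError(
                    "not enough agreed records for the requested unmappable count"
                )
            unmappable[rng.choice(agreed_idx, size=spec.n_unmappable, replace=False)] = True

        kernel = (spec.disagreement_kernel or {}).get(stratum.value, {})
        for i in range(n):
            rid = f"{_STRATUM_PREFIX[stratum]}{len(truth_rows):06d}"
            cause = causes[i]
            if unmappable[i]:
                code_a = code_b = UNMAPPABLE_CODES[rng.integers(len(UNMAPPABLE_CODES))]
            else:
                pool = pools[(stratum, cause)]
                code_a, group_a = pool[rng.integers(len(pool))]
                if agreed[i]:
                    gcodes = group_codes[group_a]
                    code_b = gcodes[rng.integers(len(gcodes))]
                else:
                    alt_dist = kernel.get(cause)
                    if alt_dist:
                        alts = [c for c in alt_dist if c != cause]
                        p = np.array([alt_dist[c] for c in alts], dtype=float)
                        alt = rng.choice(alts, p=p / p.sum())
                        alt_pool = pools[(stratum, alt)]
                        code_b, _ = alt_pool[rng.integers(len(alt_pool))]
                    else:
                        alts = [c for c in cause_ids if c != cause]
                        if alts:
                            alt = alts[rng.integers(len(alts))]
                            alt_pool = pools[(stratum, alt)]
                            code_b, _ = alt_pool[rng.integers(len(alt_pool))]
                        else:
                            # single-cause stratum: disagree by drawing from
                            # a different CMEA group of the whole table
                            others = [
                                g for g in sorted(group_codes)
                                if g != group_a and group_codes[g]
                            ]
                            g_alt = others[rng.integers(len(others))]
                            gcodes = group_codes[g_alt]
                            code_b = gcodes[rng.integers(len(gcodes))]

            toks = vocab[cause]
            picked = [toks[rng.integers(len(toks))] for _ in range(3)]
            narrative = (
                f"The deceased was a {_age_phrase(int(ages[i]))} {sexes[i]}. "
                f"The family reported {picked[0]}, {picked[1]} and {picked[2]} "
                f"in the days before death."
            )
            rec_rows.append(
                [rid, int(ages[i]), sexes[i], stratum.value]
                + symptoms[i].tolist()
                + [narrative, cause]
            )
            asg_rows.append([rid, "phys_a", "ICD10", code_a, "initial"])
            asg_rows.append([rid, "phys_b", "ICD10", code_b, "initial"])
            truth_rows.append(
                [rid, stratum.value, cause, bool(agreed[i]), bool(unmappable[i]),
                 code_a, code_b]
            )

    sym_cols = SYMPTOM_NAMES[: spec.n_symptoms]
    records = pd.DataFrame(
        rec_rows,
        columns=["record_id", "age_days", "sex", "stratum"]
        + sym_cols
        + ["narrative", "true_cause"],
    )
    assignments = pd.DataFrame(
        asg_rows, columns=["record_id", "coder_id", "code_system", "code", "phase"]
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["record_id", "stratum", "true_cause", "agreed", "unmappable",
                 "phys_a_code", "phys_b_code"],
    )
    return FixtureBundle(
        records=records,
        assignments=assignments,
        truth=truth,
        spec=spec,
        categories=categories,
        code_map=code_map,
        cmea=cmea,
        probbases=probbases,
    )


def generate_coder_outputs(
    truth: pd.DataFrame,
    confusion: ConfusionSpec,
    seed: int = 0,
    name: str = "sim",
) -> pd.DataFrame:
    """One simulated-coder assignment per record of a truth table.

    Draws each record's assigned category from the confusion row of its true
    cause (grouped by stratum and cause for speed; reproducible under seed).
    """
    rng = np.random.default_rng(seed)
    out = pd.Series(index=truth["record_id"], dtype=object)
    for stratum in (AgeStratum.ADULT, AgeStratum.CHILD, AgeStratum.NEONATE):
        sub = truth[truth["stratum"] == stratum.value]
        if sub.empty:
            continue
        for cause in sorted(sub["true_cause"].unique()):
            ids = sub.loc[sub["true_cause"] == cause, "record_id"]
            row = confusion.row(stratum, cause)
            draws = rng.choice(row.index.to_numpy(), size=len(ids), p=row.to_numpy())
            out.loc[ids] = draws
    return pd.DataFrame(
        {
            "record_id": out.index,
            "coder_id": name,
            "code_system": "CGHR10",
            "code": out.to_numpy(),
            "phase": "initial",
            "cghr": out.to_numpy(),
        }
    ).reset_index(drop=True)


# --------------------------------------------------------------------------
# fixture bundles on disk
# --------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_bundle(path, spec: CohortSpec, **tables) -> FixtureBundle:
    """Generate a cohort and write it as a fixture bundle directory.

    Layout: ``records.csv``, ``assignments.csv``, ``truth.csv``,
    ``maps/*.csv``, ``probbase_<stratum>.csv``, ``spec.yaml`` and a
    ``manifest.json`` carrying the seed and per-file SHA-256 checksums.
    Regeneration under the same spec and seed is byte-identical.
    """
    path = Path(path)
    bundle = generate_cohort(spec, **tables)
    path.mkdir(parents=True, exist_ok=True)
    (path / "maps").mkdir(exist_ok=True)

    bundle.records.to_csv(path / "records.csv", index=False, lineterminator="\n")
    bundle.assignments.to_csv(path / "assignments.csv", index=False, lineterminator="\n")
    bundle.truth.to_csv(path / "truth.csv", index=False, lineterminator="\n")

    cats = pd.DataFrame(
        [
            (s.value, c.id, c.label)
            for s in (AgeStratum.ADULT, AgeStratum.CHILD, AgeStratum.NEONATE)
            for c in bundle.categories.get(s, [])
        ],
        columns=["stratum", "id", "label"],
    )
    cats.to_csv(path / "maps" / "cghr10_categories.csv", index=False, lineterminator="\n")
    pd.DataFrame(
        [
            (e.source_system, e.range_start, e.range_end, e.age_stratum.value, e.target)
            for e in bundle.code_map.entries
        ],
        columns=["source_system", "range_start", "range_end", "age_stratum", "target_id"],
    ).to_csv(path / "maps" / "cghr10_map.csv", index=False, lineterminator="\n")
    pd.DataFrame(
        [(e.group_id, e.range_start, e.range_end) for e in bundle.cmea.entries],
        columns=["group_id", "range_start", "range_end"],
    ).to_csv(path / "maps" / "cmea10_groups.csv", index=False, lineterminator="\n")

    for stratum, pb in bundle.probbases.items():
        pb.to_csv(path / f"probbase_{stratum.value}.csv")

    with open(path / "spec.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=True)

    files = sorted(
        str(p.relative_to(path)).replace("\\", "/")
        for p in path.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "seed": spec.seed,
        "counts": {
            "records": int(len(bundle.records)),
            "assignments": int(len(bundle.assignments)),
        },
        "checksums": {f: _sha256(path / f) for f in files},
    }
    with open(path / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return bundle


def read_fixture_bundle(path, verify: bool = True) -> FixtureBundle:
    """Load a fixture bundle from disk, verifying manifest checksums."""
    from .resources import load_categories

    path = Path(path)
    with open(path / "manifest.json", encoding="utf-8") as fh:
        manifest = json.load(fh)
    if verify:
        for f, digest in manifest["checksums"].items():
            actual = _sha256(path / f)
            if actual != digest:
                raise ConfigurationError(
                    f"checksum mismatch for {f} in bundle {path}"
                )
    with open(path / "spec.yaml", encoding="utf-8") as fh:
        spec = CohortSpec.from_dict(yaml.safe_load(fh))
    categories = load_categories(path / "maps" / "cghr10_categories.csv")
    code_map = CodeMapTable.from_csv(path / "maps" / "cghr10_map.csv", categories)
    cmea = CmeaGroupTable.from_csv(path / "maps" / "cmea10_groups.csv")
    probbases = {}
    for s in AgeStratum:
        pb_path = path / f"probbase_{s.value}.csv"
        if pb_path.exists():
            probbases[s] = Probbase.from_csv(pb_path)
    return FixtureBundle(
        records=pd.read_csv(path / "records.csv"),
        assignments=pd.read_csv(path / "assignments.csv"),
        truth=pd.read_csv(path / "truth.csv"),
        spec=spec,
        categories=categories,
        code_map=code_map,
        cmea=cmea,
        probbases=probbases,
    )
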