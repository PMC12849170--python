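# Methods

This note documents the models, conventions and design choices behind
`vaeval`, in the spirit of a statistical package's methods documentation.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design being modelled

Each death is reviewed independently by two physicians who assign ICD-10
codes. Agreement is judged at the level of CMEA-10 groups — inclusive
ranges of clinically related ICD-10 codes — not exact codes: a record is in
agreement iff both codes fall in the same non-missing group. Disagreements
enter reconciliation (each physician may retain their code, adopt the
other's, or assign a new one) and, if still unresolved, senior
adjudication. The evaluation pipeline uses only records with *initial*
agreement whose code maps to a valid CGHR-10 category; reconciliation and
adjudication are implemented as simulations for synthetic cohorts and play
no role in scoring. A code outside every CMEA-10 group never counts as
agreement, even when both physicians give the identical out-of-table code;
this is a convention of this implementation, since the underlying workflow
description does not settle the case.

## Age strata and code systems

Age at death in days assigns each record to exactly one stratum: neonate
(< 28 days), child (28 days to < 12 years), adult (12 years to completed
age 69). One year = 365.25 days, one month = 30.44 days throughout. Ages
of 70+ completed years are outside the design and raise an error rather
than being coerced; callers exclude and log them.

ICD-10 codes normalize to `letter + two digits + optional .subcode`;
separator and case variants (`j45-9`, `J459`) canonicalize to `J45.9` and
normalization is idempotent. Ranges are inclusive on both ends in tabular
order (letter, digits numerically, subcode numerically where numeric); a
bare code sorts before its subcoded children and a range ending at a bare
code includes all its children, so `J45.9` lies inside `A00–J45`. WHO-VA-
2016 cause codes (dotted numeric tokens) follow the same bare-prefix
conventions and flow through a crosswalk table of the same shape.

The CGHR-10 category resource carries exactly 19 adult, 10 child and 7
neonatal categories (stillbirth is a first-class neonatal category). The
packaged code lists are a reconstruction from published cause names — the
authoritative tables are not in the public main text — and are deliberately
editable CSVs; the 19th adult category (homicide/violence) is a structural
filler for a cause with zero records in the published figures. The CMEA-10
groups in the default resource are strictly finer than the CGHR-10 ranges,
which yields the invariant the filter relies on: two codes in one CMEA-10
group always map to the same CGHR-10 category, so "agreed" implies an
unambiguous reference category.

## Metrics

**PCCC.** With one assigned cause per record (the k = 1 case of
chance-corrected concordance; every coder here emits a single COD), the
concordance fraction C rescales to `PCCC = (C − 1/N)/(1 − 1/N)` with N the
stratum's category count. Negative raw values are clamped to 0 for
reporting — matching the reporting convention of the literature this
mirrors — and the raw value is retained alongside. Per-cause PCCC
conditions on the *reference* (physician) cause, i.e. a sensitivity-style
restriction; conditioning on the predicted cause is available behind
`EvalConfig(condition_on="predicted")` since the published convention is
not stated.

**CSMF accuracy.** `1 − Σ|pred_j − ref_j| / (2(1 − min_j ref_j))`, the
canonical normalization by the maximum total error attainable (all mass on
the rarest reference cause). The reference CSMF is computed from the
physician assignments of the evaluated subset itself, never from external
totals. A reference concentrated on a single cause is rejected as
degenerate. Results are clamped to [0, 1] against floating-point drift.

**Bootstrap.** Percentile method (not BCa), resampling the (reference,
predicted) record pair with replacement, B = 1000 and level 0.95 by
default; the seed is recorded in every output table. For cause-restricted
PCCC the restricted subset is the resampling population. Resamples on
which a metric is undefined (e.g. a degenerate reference) are redrawn with
a capped retry count. The percentile method is the simplest estimator
consistent with "bootstrapping, 1000 resamples with replacement", and the
acceptance suite verifies ≥ 90% empirical coverage of the true PCCC over
200 nested Monte-Carlo repetitions at n = 500.

**Pooling across strata.** Overall (and fine-age-band) scores pool records
whose cause lists differ by stratum; labels are qualified as
`stratum:category`, and N is the size of the pooled list over the strata
present (36 for the default resource; a band fully inside one stratum uses
that stratum's N). The pooled concordance equals the n-weighted mean of
per-stratum concordances (an exact identity, asserted in tests); the
chance-correction term is the only pooling convention with any freedom,
and this choice is recorded in output metadata via the n column.

## Age bands

Neonates: 0–6 and 7–27 days. From 28 days to one year, five-month bands
anchored at 28 days: [28 d, 6 mo), [6 mo, 11 mo), and the 11-month
remainder. From one year, five-year bands anchored at 1 year: [1, 5),
[5, 10), … [65, 70). Published analyses give the band widths but not the
anchors; these edges are this package's convention, chosen so the bands
partition the full study age range exactly (property-tested). Bands are
age-based, not stratum-based, so a band such as 10–14 years can straddle
the child/adult boundary; its N follows the pooling rule above.

## Coders

**Naive-Bayes coder.** `posterior_j ∝ prior_j · Π_i cond_ji^{s_i} (1 −
cond_ji)^{1−s_i}` over observed symptoms, computed in log space; missing
symptoms contribute nothing, so an all-missing vector returns the priors.
Absent symptoms contribute the (1 − p) complement by default
(`absence_mode="complement"`, the proper likelihood); `"ignore"` skips
them, matching the dialect of some questionnaire-driven coders — the
published description does not specify, so both are available. Probbase
entries must lie strictly inside (0, 1) so no single symptom can zero out
a cause. The default `indeterminate_threshold` is 0 (always assign the
argmax, ties broken by fixed cause order) because the evaluation scores
every record; when a positive threshold is set, indeterminate outputs map
to the stratum's ill-defined category for scoring.

**LLM adapter.** Only the verbatim prompt template (age, sex, narrative
substituted) and its parser ship here; no network client. External coders
plug in behind the same `assign(record) -> CauseAssignment` contract.
Hierarchical-Bayes MCMC coders and questionnaire-format conversion are out
of scope by design.

**Simulated coder.** Draws the assigned category from the confusion row of
the record's true cause; identity, uniform, and diagonal-c constructors
cover the controlled experiments (a diagonal-c coder's expected overall
PCCC is exactly (c − 1/N)/(1 − 1/N), the closed form the acceptance suite
recovers). Coders that emit categories directly use the `CGHR10` code
system token rather than passing through a code map.

## Synthetic cohorts

The generator emulates the *structure* the analysis assumes: per-stratum
sizes; per-stratum cause distributions; symptoms drawn Bernoulli from the
stratum probbase row of the true cause; template narratives (cause-keyword
tokens plus a demographic clause — adequate for prompt-builder testing, no
claim of clinical realism); physician A's code drawn uniformly from the
true cause's configured ICD-10 ranges; physician B's code drawn from A's
CMEA-10 group with the per-cause agreement probability, otherwise from
another cause via the disagreement kernel (uniform over other causes by
default); and a configurable number of agreed records given an identical
code from a CMEA group outside the CGHR-10 map (the "agreed but
unmappable" channel). Ages are uniform within stratum bounds — no
demographic realism is claimed, which also means age-band performance
curves from synthetic cohorts carry no information about real age trends.

Default study conditions: the published-shape spec fixes the published
structure — 11,920 initial records filtering to 6,942 agreed and 6,939
agreed-and-valid (3,826 adult / 2,636 child / 477 neonatal) — using an
exact-agreed-count mode (a uniform random subset of exactly k records per
stratum agrees), because published counts are exact while per-record
Bernoulli draws would only approximate them. The per-stratum split of the
~5,000 disagreeing records is not published and is allocated roughly
proportionally. Per-cause agreement rates quoted in the source (malaria
0.77 adult / 0.85 child, pneumonia 0.34/0.31, cancers 0.20, road and other
injuries 0.75/0.72, child injuries 0.76, nutritional 0.39, unspecified
infections 0.37, stillbirth 0.76) anchor the default stochastic rates;
unquoted causes sit at 0.40–0.60 inside the published 20–85% range. Cause
mixes are illustrative, chosen consistent with the published low-count
exclusions (a handful of adult suicides, one or two congenital anomaly
records, ~5 neonatal "other" records); the true per-cause distributions
are not in the public text. Passing tests on these cohorts demonstrate
pipeline correctness and metric calibration, not the performance of any
real coder on real data.

Fixture bundles written to disk are byte-identical under identical spec
and seed (fixed float formats, LF line endings, no timestamps) and carry a
manifest with per-file SHA-256 checksums, verified on reread.

## Numerical and degenerate-input conventions

Probbase priors renormalize on CSV reread to absorb rounding; posterior
normalization is exact to 1e-9 (property-tested). Exact posterior ties
break by fixed cause order. Empty symptom evidence, unmapped codes, empty
strata, single-cause references, and metric-undefined bootstrap resamples
each have explicit behaviour (priors, `None` sentinel, exclusion with
reason, configuration error, redraw) rather than silent coercion. Cause
strata with fewer than `min_n = 10` records are flagged excluded — a
conservative default reproducing all published exclusions (which reported
n ≤ 5 without stating a threshold) — and exclusion never alters any other
stratum's values.

## Problem sizes

Default test and acceptance runs use cohorts of 200–12,000 records,
B = 1000 bootstrap resamples, 200 coverage repetitions, and exhaustive
metric-oracle sweeps over all instances with n ≤ 6 records and ≤ 3 causes
(ordered pairs to n = 4; order-free joint count matrices, which both
metrics depend on exclusively, to n = 6). These sizes were chosen as the
smallest at which the stochastic checks have comfortable Monte-Carlo
margins.

## Known limitations

* The shipped CGHR-10/CMEA-10 tables are reconstructions; real analyses
  must supply authoritative tables (the loaders accept paths).
* The naive-Bayes coder does not claim fidelity to any published
  propagation/normalization variant of field coders beyond the standard
  naive-Bayes form with the absence-mode toggle.
* No inter-rater statistics beyond the agreement fraction (e.g. kappa),
  no ranked/top-k concordance, no Bayesian CSMF uncertainty.
* Narratives are token templates; nothing about real LLM behaviour can be
  inferred from the simulated coder.
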