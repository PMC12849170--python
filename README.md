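# vaeval

Evaluation pipeline for **computer-coded verbal autopsy (VA)**.

In settings where most deaths occur outside health facilities, verbal
autopsies — structured interviews with relatives of the deceased — are the
main source of cause-of-death (COD) data. Best practice is dual physician
coding: two physicians independently assign an ICD-10 code to each record,
agreement is judged at the level of CMEA-10 groups (ranges of clinically
related ICD-10 codes), and disagreements go through reconciliation and
senior adjudication. Automated coders — naive-Bayes symptom algorithms,
hierarchical-Bayes models, and more recently large language models prompted
with the free-text narrative — promise scalable, reproducible alternatives,
but need rigorous comparison against the physician standard.

`vaeval` packages that comparison as a reusable pipeline for
epidemiologists and VA methodologists:

* **Cause-code standardization** — ICD-10 parsing/normalization, mapping of
  ICD-10 and WHO-VA-2016 codes to the compact CGHR-10 cause list
  (19 adult / 10 child / 7 neonatal categories) via editable CSV range
  tables, and CMEA-10 agreement grouping.
* **Physician workflow** — dual-coding agreement, simulated
  reconciliation/adjudication, and the filter to physician-agreed records
  with a valid CGHR-10 category, with a full audit trail.
* **Coders behind one adapter contract** — a naive-Bayes
  maximum-probability coder driven by a probbase (cause priors plus
  P(symptom | cause)), the narrative prompt template for LLM coders (no API
  calls; plug in your own client), and a confusion-matrix-driven simulated
  coder for controlled experiments.
* **Metrics** — individual-level partial chance-corrected concordance and
  population-level CSMF accuracy, with percentile-bootstrap confidence
  intervals, stratified overall / by age group / by cause / by fine age
  band, with low-count exclusions and per-stratum model ranking.
* **Synthetic cohorts** — a generator that reproduces the structure these
  analyses assume (stratum sizes, per-cause physician agreement rates,
  probbase-driven symptoms, out-of-map codes), so the whole pipeline is
  testable without any restricted data.

## The metrics

With a single assigned cause per death, the concordance fraction `C` is the
share of records where the coder matches the physician reference. Chance
correction over a cause list of size `N` gives

    PCCC = (C − 1/N) / (1 − 1/N)

so chance-level assignment scores 0 and perfect assignment scores 1
(negative raw values are floored at 0 for reporting). At the population
level, with cause-specific mortality fractions (CSMFs) `pred_j` and
`ref_j`,

    CSMF accuracy = 1 − Σ_j |pred_j − ref_j| / (2 (1 − min_j ref_j))

which is 1 for identical fraction vectors and exactly 0 for the worst-case
predictor that puts all mass on the rarest reference cause. Confidence
intervals are percentile bootstrap over records (1000 resamples with
replacement by default).

## Worked example

Generate a cohort with the reference study's structure (11,920 records,
three age strata), evaluate three coders, and read the summary:

```bash
vaeval generate --published-shape --seed 1 --out bundle
cat > config.yaml <<EOF
bundle: bundle
coders:
  - name: identity
    type: identity
  - name: bayes
    type: bayes
  - name: sim_llm
    type: simulated
    diagonal: 0.7
bootstrap_B: 1000
seed: 1
EOF
vaeval evaluate --config config.yaml --out results
```

which logs:

```
INFO vaeval: filter chain: 11920 total -> 6942 agreed -> 6939 agreed-and-valid
INFO vaeval: overall PCCC identity     1.000 (1.000-1.000, n=6939)
INFO vaeval: overall PCCC bayes        0.783 (0.773-0.793, n=6939)
INFO vaeval: overall PCCC sim_llm      0.690 (0.679-0.702, n=6939)
```

Reading this: of 11,920 synthetic records, 6,942 have initial physician
agreement at the CMEA-10 level and 6,939 of those map to a valid CGHR-10
category — the evaluation denominator. The `identity` coder (a copy of the
physician reference) scores PCCC 1.0 by construction, a sanity anchor. The
naive-Bayes coder, reading the probbase-generated symptom vectors, reaches
0.783; the simulated coder built with 70% diagonal confusion lands at
0.690, matching its closed-form expectation (0.7 − 1/N)/(1 − 1/N) within
sampling error. `results/results.csv` holds the full stratified table
(per age group, per cause with low-n exclusions, per five-month/five-year
age band), each row with its bootstrap CI, per-stratum coder rank, and the
max − min PCCC range across coders; `results/audit.json` holds the filter
audit.

The same pipeline is a library:

```python
from vaeval import (published_cohort_spec, generate_cohort, filter_agreed_valid,
                    evaluate_all, EvalConfig)

bundle = generate_cohort(published_cohort_spec(seed=1))
kept, audit = filter_agreed_valid(bundle.records, bundle.assignments,
                                  bundle.cmea, bundle.code_map)
reference = kept.set_index("record_id")["reference_cghr"]
results = evaluate_all(kept, {"identity": reference.copy()},
                       bundle.categories, config=EvalConfig(seed=1))
print(results.to_frame().head())
```

## Data

No real VA data ships with this package. The CGHR-10 category lists,
ICD-10 ranges and CMEA-10 groups under `src/vaeval/data/` are a
reconstruction from published cause names, intended as editable defaults —
point the loaders in `vaeval.resources` at authoritative tables for real
analyses. The packaged probbases are synthetic (see
`vaeval.synthetic.make_synthetic_probbase`) and carry no claim of fidelity
to any published expert probbase.
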