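"""Age bands, stratified evaluation, exclusions, and ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vaeval.codes import ADULT_UPPER_DAYS, AgeStratum
from vaeval.errors import ContractError
from vaeval.evaluate import (
    EvalConfig,
    EvalResult,
    build_age_bands,
    evaluate_all,
    exclude_low_n,
    rank_and_range,
)
from vaeval.metrics import MetricValue, concordance_fraction


class TestAgeBands:
    @pytest.mark.parametrize(
        "age_days,label",
        [
            (3, "0-6 days"),
            (6, "0-6 days"),
            (7, "7-27 days"),
            (27, "7-27 days"),
            (28, "1-5 months"),
            (int(10 * 30.44), "6-10 months"),  # age 10 months
            (350, "11 months"),
            (366, "1-4 years"),
            (int(14 * 365.25), "10-14 years"),  # age 14 years
            (25000, "65-69 years"),
        ],
    )
    def test_band_assignment(self, age_days, label):
        assert build_age_bands().band_of(age_days) == label

    @given(st.integers(0, ADULT_UPPER_DAYS - 1))
    def test_partition_every_age_in_exactly_one_band(self, age_days):
        bands = build_age_bands()
        hits = [
            b.label
            for b in bands.bands
            if b.lower_days <= age_days < b.upper_days
        ]
        assert len(hits) == 1
        assert bands.band_of(age_days) == hits[0]

    def test_neonatal_bands_exactly_two(self):
        labels = build_age_bands().labels
        assert labels[:2] == ["0-6 days", "7-27 days"]


def _small_eval(small_bundle, small_kept, coders=None, **cfg):
    from vaeval.synthetic import generate_coder_outputs
    from vaeval.coders import ConfusionSpec, diagonal_confusion, identity_confusion

    kept, _ = small_kept
    ref = kept.set_index("record_id")["reference_cghr"]
    truth = small_bundle.truth[small_bundle.truth["record_id"].isin(kept["record_id"])]
    outputs = {"identity": ref.copy()}
    if coders:
        for name, c in coders.items():
            spec = ConfusionSpec(
                {
                    s: diagonal_confusion(
                        [cat.id for cat in small_bundle.categories[s]], c
                    )
                    for s in AgeStratum
                }
            )
            outputs[name] = (
                generate_coder_outputs(truth, spec, seed=hash(name) % 2**31, name=name)
                .set_index("record_id")["cghr"]
            )
    config = EvalConfig(bootstrap_B=cfg.pop("bootstrap_B", 50), **cfg)
    return evaluate_all(kept, outputs, small_bundle.categories, config=config), kept


class TestEvaluateAll:
    def test_identity_coder_scores_one_everywhere(self, small_bundle, small_kept):
        results, _ = _small_eval(small_bundle, small_kept)
        for r in results.select(coder="identity"):
            if r.excluded:
                continue
            assert r.pccc.point == pytest.approx(1.0)
            if r.csmf_accuracy is not None:
                assert r.csmf_accuracy.point == pytest.approx(1.0)

    def test_identity_dominates_noisy_coder_in_every_stratum(
        self, small_bundle, small_kept
    ):
        results, _ = _small_eval(small_bundle, small_kept, coders={"noisy": 0.5})
        for kind in ("overall", "age_group"):
            for key in {r.key for r in results.select(kind=kind)}:
                cell = results.select(kind=kind, key=key)
                ordered, rng = rank_and_range(cell)
                assert ordered[0][0] == "identity"
                assert rng >= 0

    def test_stratum_concordance_ordering_recovered(self, small_bundle, small_kept):
        """A coder that is accurate for adults (c=0.9) and weak for children
        (c=0.5) must show adult PCCC > child PCCC."""
        from vaeval.synthetic import generate_coder_outputs
        from vaeval.coders import ConfusionSpec, diagonal_confusion

        kept, _ = small_kept
        ref = kept.set_index("record_id")["reference_cghr"]
        truth = small_bundle.truth[
            small_bundle.truth["record_id"].isin(kept["record_id"])
        ]
        spec = ConfusionSpec(
            {
                s: diagonal_confusion(
                    [c.id for c in small_bundle.categories[s]],
                    {"adult": 0.9, "child": 0.5, "neonate": 0.7}[s.value],
                )
                for s in AgeStratum
            }
        )
        out = generate_coder_outputs(truth, spec, seed=21, name="mixed").set_index(
            "record_id"
        )["cghr"]
        results = evaluate_all(
            kept,
            {"mixed": out},
            small_bundle.categories,
            config=EvalConfig(bootstrap_B=50, seed=2),
        )
        adult = results.select(kind="age_group", key="adult")[0].pccc.point
        child = results.select(kind="age_group", key="child")[0].pccc.point
        assert adult > child

    def test_overall_concordance_is_weighted_mean_of_groups(
        self, small_bundle, small_kept
    ):
        """Exact identity: pooled concordance equals the n-weighted mean of
        per-age-group concordances."""
        results, kept = _small_eval(small_bundle, small_kept, coders={"noisy": 0.6})
        from vaeval.synthetic import generate_coder_outputs
        from vaeval.coders import ConfusionSpec, diagonal_confusion

        truth = small_bundle.truth[
            small_bundle.truth["record_id"].isin(kept["record_id"])
        ]
        spec = ConfusionSpec(
            {
                s: diagonal_confusion([c.id for c in small_bundle.categories[s]], 0.6)
                for s in AgeStratum
            }
        )
        out = generate_coder_outputs(truth, spec, seed=33).set_index("record_id")["cghr"]
        ref = kept.set_index("record_id")["reference_cghr"]
        out = out.reindex(ref.index)
        overall_c = concordance_fraction(ref.to_numpy(), out.to_numpy())
        weighted = 0.0
        for s in AgeStratum:
            mask = (kept.set_index("record_id")["stratum"] == s.value).to_numpy()
            weighted += mask.sum() * concordance_fraction(
                ref.to_numpy()[mask], out.to_numpy()[mask]
            )
        assert overall_c == pytest.approx(weighted / len(ref))

    def test_missing_coder_coverage_rejected(self, small_bundle, small_kept):
        kept, _ = small_kept
        ref = kept.set_index("record_id")["reference_cghr"]
        with pytest.raises(ContractError, match="missing assignments"):
            evaluate_all(
                kept,
                {"partial": ref.iloc[:-5]},
                small_bundle.categories,
                config=EvalConfig(bootstrap_B=10),
            )

    def test_band_counts_partition_cohort(self, small_bundle, small_kept):
        results, kept = _small_eval(small_bundle, small_kept)
        band_n = sum(r.n for r in results.select(kind="age_band", coder="identity"))
        assert band_n == len(kept)


class TestExclusions:
    def _fake_results(self, ns):
        from vaeval.evaluate import EvalResults

        res = [
            EvalResult("age_group", "adult", "m", sum(ns)),
        ] + [
            EvalResult(
                "cause", f"adult:c{i}", "m", n,
                pccc=MetricValue(point=0.5, n=n),
            )
            for i, n in enumerate(ns)
        ]
        return EvalResults(res, EvalConfig(bootstrap_B=10))

    def test_low_n_causes_flagged(self):
        out = exclude_low_n(self._fake_results([3, 5, 50]), min_n=10)
        flags = {r.key: r.excluded for r in out.results if r.kind == "cause"}
        assert flags == {"adult:c0": True, "adult:c1": True, "adult:c2": False}

    def test_excluded_strata_carry_no_metric_values(self):
        out = exclude_low_n(self._fake_results([3, 50]), min_n=10)
        excluded = [r for r in out.results if r.excluded and r.kind == "cause"]
        assert all(r.pccc is None and r.csmf_accuracy is None for r in excluded)

    def test_exclusion_leaves_other_values_untouched(self):
        before = self._fake_results([3, 50])
        after = exclude_low_n(before, min_n=10)
        kept_before = [r for r in before.results if r.kind == "cause" and r.n >= 10]
        kept_after = [r for r in after.results if r.kind == "cause" and not r.excluded]
        assert [r.pccc.point for r in kept_before] == [r.pccc.point for r in kept_after]

    def test_nothing_excluded_above_threshold(self):
        out = exclude_low_n(self._fake_results([20, 50]), min_n=10)
        assert not any(r.excluded for r in out.results)


class TestRankAndRange:
    def _cell(self, points):
        return [
            EvalResult("age_group", "adult", f"m{i}", 100,
                       pccc=MetricValue(point=p, n=100))
            for i, p in enumerate(points)
        ]

    def test_two_coders(self):
        ordered, rng = rank_and_range(self._cell([0.9, 0.4]))
        assert ordered == [("m0", 0.9), ("m1", 0.4)] and rng == pytest.approx(0.5)

    def test_single_coder_range_zero(self):
        _, rng = rank_and_range(self._cell([0.7]))
        assert rng == 0.0

    def test_five_coders_match_brute_force(self):
        points = [0.31, 0.72, 0.11, 0.55, 0.93]
        ordered, rng = rank_and_range(self._cell(points))
        assert [p for _, p in ordered] == sorted(points, reverse=True)
        assert rng == pytest.approx(max(points) - min(points))

    def test_ties_broken_by_name(self):
        ordered, _ = rank_and_range(self._cell([0.5, 0.5]))
        assert [c for c, _ in ordered] == ["m0", "m1"]

    def test_mixed_strata_rejected(self):
        cell = self._cell([0.5]) + [
            EvalResult("age_group", "child", "x", 10, pccc=MetricValue(point=0.1, n=10))
        ]
        with pytest.raises(ContractError):
            rank_and_range(cell)
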