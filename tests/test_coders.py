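"""Naive-Bayes coder, prompt template, and confusion-driven simulated coder."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vaeval.coders import (
    INDETERMINATE,
    BayesCoder,
    ConfusionSpec,
    Probbase,
    SimulatedCoder,
    bayes_assign,
    bayes_posterior,
    build_prompt,
    diagonal_confusion,
    identity_confusion,
    parse_prompt,
    uniform_confusion,
)
from vaeval.errors import ConfigurationError, ValidationError


def _pb(priors, cond, causes=None, symptoms=None):
    cond = np.asarray(cond, dtype=float)
    causes = causes or [f"c{i}" for i in range(cond.shape[0])]
    symptoms = symptoms or [f"s{i}" for i in range(cond.shape[1])]
    return Probbase(causes=causes, symptoms=symptoms, priors=np.asarray(priors), cond=cond)


class TestBayesPosterior:
    def test_hand_computed_two_cause_case(self):
        """priors (.5,.5), P(s|c) = (.9,.1), symptom present:
        posterior = (.45, .05)/.5 = (.9, .1)."""
        pb = _pb([0.5, 0.5], [[0.9], [0.1]])
        post = bayes_posterior([1.0], pb)
        assert np.allclose(post, [0.9, 0.1])

    def test_identical_conditionals_give_uniform_posterior(self):
        pb = _pb([0.25] * 4, np.full((4, 3), 0.4))
        post = bayes_posterior([1, 0, 1], pb)
        assert np.allclose(post, 0.25)

    def test_all_missing_returns_priors(self):
        pb = _pb([0.7, 0.2, 0.1], np.full((3, 4), 0.3))
        post = bayes_posterior([np.nan] * 4, pb)
        assert np.allclose(post, [0.7, 0.2, 0.1])

    def test_absence_mode_ignore_skips_absent_symptoms(self):
        pb = _pb([0.5, 0.5], [[0.9, 0.2], [0.1, 0.8]])
        post = bayes_posterior([1, 0], pb, absence_mode="ignore")
        # only the present symptom contributes
        assert np.allclose(post, [0.9, 0.1])

    def test_log_and_direct_space_agree(self):
        """Oracle equivalence: direct-probability product matches the
        log-space implementation on a small instance."""
        rng = np.random.default_rng(5)
        cond = rng.uniform(0.05, 0.95, size=(4, 6))
        priors = rng.dirichlet(np.ones(4))
        pb = _pb(priors, cond)
        s = np.array([1, 0, 1, np.nan, 0, 1], dtype=float)
        direct = priors.copy()
        for j in range(4):
            for i, v in enumerate(s):
                if v == 1:
                    direct[j] *= cond[j, i]
                elif v == 0:
                    direct[j] *= 1 - cond[j, i]
        direct /= direct.sum()
        assert np.allclose(bayes_posterior(s, pb), direct, atol=1e-9)

    def test_invalid_entries_rejected(self):
        pb = _pb([0.5, 0.5], [[0.9], [0.1]])
        with pytest.raises(ValidationError):
            bayes_posterior([2.0], pb)


@st.composite
def _probbase_and_symptoms(draw):
    n_c = draw(st.integers(2, 5))
    n_s = draw(st.integers(1, 6))
    rng = np.random.default_rng(draw(st.integers(0, 2**16)))
    pb = _pb(rng.dirichlet(np.ones(n_c)), rng.uniform(0.05, 0.95, size=(n_c, n_s)))
    s = np.array(
        draw(st.lists(st.sampled_from([0.0, 1.0, np.nan]), min_size=n_s, max_size=n_s))
    )
    return pb, s


class TestBayesProperties:
    @given(_probbase_and_symptoms())
    def test_posterior_normalized(self, case):
        pb, s = case
        assert abs(bayes_posterior(s, pb).sum() - 1.0) < 1e-9

    @given(_probbase_and_symptoms())
    def test_symptom_permutation_invariance(self, case):
        """Permuting symptom columns consistently in probbase and vector
        leaves the posterior unchanged."""
        pb, s = case
        perm = np.random.default_rng(0).permutation(len(pb.symptoms))
        pb2 = _pb(pb.priors, pb.cond[:, perm])
        assert np.allclose(bayes_posterior(s, pb), bayes_posterior(s[perm], pb2))

    @given(_probbase_and_symptoms(), st.integers(0, 4))
    def test_monotone_in_conditional_of_present_symptom(self, case, j_raw):
        """Raising P(symptom|cause j) for an observed-present symptom never
        lowers cause j's posterior."""
        pb, s = case
        present = np.flatnonzero(s == 1.0)
        if present.size == 0:
            return
        i = int(present[0])
        j = j_raw % len(pb.causes)
        post_before = bayes_posterior(s, pb)[j]
        cond2 = pb.cond.copy()
        cond2[j, i] = min(0.99, cond2[j, i] + 0.3)
        post_after = bayes_posterior(s, _pb(pb.priors, cond2))[j]
        assert post_after >= post_before - 1e-12


class TestBayesAssign:
    def test_clear_argmax(self):
        assert bayes_assign([0.7, 0.3], ["a", "b"], 0.4) == "a"

    def test_below_threshold_indeterminate(self):
        assert bayes_assign([0.34, 0.33, 0.33], ["a", "b", "c"], 0.5) == INDETERMINATE

    def test_exact_tie_breaks_by_category_order(self):
        assert bayes_assign([0.5, 0.5], ["b", "a"], 0.0) == "b"

    def test_coder_maps_indeterminate_to_ill_defined(self):
        pb = _pb([0.5, 0.5], [[0.5], [0.5]], causes=["x", "ill_defined"], symptoms=["fever"])
        coder = BayesCoder({"adult": pb}, indeterminate_threshold=0.9)
        rec = {"record_id": "r1", "stratum": "adult", "fever": 1}
        assert coder.assign(rec).cghr == "ill_defined"


class TestPromptTemplate:
    def test_substitution(self):
        p = build_prompt(34, "female", "She had fever for two weeks.")
        assert p == (
            "Determine the underlying cause of death and provide the most "
            "probable ICD-10 code for a verbal autopsy narrative of a 34 "
            "years old female death in Sierra Leone: She had fever for two weeks."
        )

    def test_round_trip_recovers_inputs(self):
        age, sex, narrative = parse_prompt(build_prompt(7, "male", "Sudden onset."))
        assert (age, sex, narrative) == ("7", "male", "Sudden onset.")

    def test_distinct_narratives_give_distinct_prompts(self):
        assert build_prompt(1, "male", "a") != build_prompt(1, "male", "b")

    def test_empty_narrative_rejected(self):
        with pytest.raises(ValidationError):
            build_prompt(34, "female", "  ")


class TestSimulatedCoder:
    def _record(self, cause="a"):
        return {"record_id": "r", "stratum": "adult", "true_cause": cause}

    def test_identity_confusion_reproduces_truth(self):
        spec = ConfusionSpec({"adult": identity_confusion(["a", "b", "c"])})
        coder = SimulatedCoder(spec, seed=0)
        for cause in "abc":
            assert coder.assign(self._record(cause)).cghr == cause

    def test_point_mass_row_always_assigns_that_cause(self):
        m = pd.DataFrame(
            [[0, 1.0], [0, 1.0]], index=["a", "b"], columns=["a", "b"], dtype=float
        )
        coder = SimulatedCoder(ConfusionSpec({"adult": m}), seed=0)
        assert all(coder.assign(self._record("a")).cghr == "b" for _ in range(20))

    def test_diagonal_rate_within_binomial_envelope(self):
        """Monte-Carlo: 0.8-diagonal confusion hits the true cause at a rate
        inside the 99% binomial interval over 10,000 draws."""
        spec = ConfusionSpec({"adult": diagonal_confusion(list("abcde"), 0.8)})
        coder = SimulatedCoder(spec, seed=7)
        n = 10_000
        hits = sum(coder.assign(self._record("c")).cghr == "c" for _ in range(n))
        sd = np.sqrt(0.8 * 0.2 * n)
        assert abs(hits - 0.8 * n) < 2.6 * sd

    def test_unknown_true_cause_rejected(self):
        spec = ConfusionSpec({"adult": identity_confusion(["a"])})
        with pytest.raises(ConfigurationError):
            SimulatedCoder(spec).assign(self._record("zzz"))

    def test_rows_must_sum_to_one(self):
        m = pd.DataFrame([[0.5, 0.4], [0.5, 0.5]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ConfigurationError):
            ConfusionSpec({"adult": m})

    def test_uniform_confusion_is_square_and_stochastic(self):
        m = uniform_confusion(list("abcd"))
        assert np.allclose(m.sum(axis=1), 1.0) and m.shape == (4, 4)


class TestProbbaseValidation:
    def test_priors_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            _pb([0.6, 0.6], [[0.5], [0.5]])

    def test_conditionals_strictly_inside_unit_interval(self):
        with pytest.raises(ConfigurationError):
            _pb([0.5, 0.5], [[1.0], [0.5]])

    def test_csv_round_trip(self, tmp_path):
        from vaeval.synthetic import make_synthetic_probbase

        pb = make_synthetic_probbase(["a", "b", "c"], ["s1", "s2"], seed=3)
        path = tmp_path / "pb.csv"
        pb.to_csv(path)
        back = Probbase.from_csv(path)
        assert back.causes == pb.causes and back.symptoms == pb.symptoms
        assert np.allclose(back.cond, pb.cond, atol=1e-6)
        assert abs(back.priors.sum() - 1.0) < 1e-12
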