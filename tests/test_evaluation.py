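"""AUC, permutation significance, p-value combination, responder rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hforate.evaluation import (
    PatientSummary,
    WindowSummary,
    bootstrap_pvalue,
    classify_responder,
    feature_frequency,
    harmonic_mean_p,
    responder_proportion_ci,
    roc_auc,
    summarize_patient,
)
from hforate.model import FittedModel, RepeatResult


def _model(coef):
    coef = np.asarray(coef, dtype=float)
    return FittedModel(0.0, coef, 0.1, 2, bool(np.any(coef != 0)),
                       np.zeros(16), np.ones(16))


class TestRocAuc:
    def test_enumerated_four_pair_example(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([0, 0, 1, 1])
        # pairs: (.35>.1), (.35<.4), (.8>.1), (.8>.4) -> 3/4
        assert roc_auc(scores, labels).auc == 0.75

    def test_all_ties_half(self):
        assert roc_auc(np.ones(6), [0, 0, 0, 1, 1, 1]).auc == 0.5

    def test_perfect_separation_one(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]).auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_sklearn_with_ties(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        for _ in range(10):
            scores = rng.integers(0, 5, 30) / 4.0  # many ties
            labels = rng.integers(0, 2, 30)
            if labels.min() == labels.max():
                continue
            assert roc_auc(scores, labels).auc == pytest.approx(
                roc_auc_score(labels, scores))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_score_negation_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.standard_normal(20)  # tie-free a.s.
        labels = np.r_[np.zeros(12), np.ones(8)]
        a = roc_auc(scores, labels).auc
        b = roc_auc(-scores, labels).auc
        assert a + b == pytest.approx(1.0)


class TestBootstrapPvalue:
    def test_null_p_uniform_mean_half(self):
        rng = np.random.default_rng(1)
        ps = []
        for seed in range(100):
            scores = rng.standard_normal(30)
            labels = np.r_[np.zeros(24), np.ones(6)]
            ps.append(bootstrap_pvalue(scores, labels, n_perm=199,
                                       seed=seed).p_value)
        assert abs(np.mean(ps) - 0.5) < 0.1

    def test_perfect_separation_significant(self):
        scores = np.r_[np.linspace(0, 0.4, 30), np.linspace(0.6, 1.0, 5)]
        labels = np.r_[np.zeros(30), np.ones(5)]
        res = bootstrap_pvalue(scores, labels, n_perm=1000, seed=0)
        assert res.observed_auc == 1.0
        assert res.p_value <= 0.05

    def test_plus_one_floor(self):
        scores = np.r_[np.zeros(20), np.ones(20)]
        labels = np.r_[np.zeros(20), np.ones(20)]
        res = bootstrap_pvalue(scores, labels, n_perm=400, seed=0)
        assert res.p_value >= 1.0 / 401

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        scores = rng.random(25)
        labels = rng.integers(0, 2, 25)
        labels[:2] = [0, 1]
        a = bootstrap_pvalue(scores, labels, n_perm=300, seed=9)
        b = bootstrap_pvalue(np.exp(3 * scores), labels, n_perm=300, seed=9)
        assert a.p_value == b.p_value

    def test_constant_scores_p_one(self):
        # a non-converged model scores everything identically: chance AUC,
        # and every permutation ties it, so p = 1
        res = bootstrap_pvalue(np.full(20, 0.5), np.r_[np.zeros(15),
                                                       np.ones(5)],
                               n_perm=200, seed=3)
        assert res.observed_auc == 0.5
        assert res.p_value == 1.0

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(4)
        scores, labels = rng.random(20), rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        assert (bootstrap_pvalue(scores, labels, 200, seed=5).p_value
                == bootstrap_pvalue(scores, labels, 200, seed=5).p_value)


class TestHarmonicMeanP:
    def test_identical_inputs(self):
        assert harmonic_mean_p([0.05, 0.05, 0.05]) == pytest.approx(0.05)

    def test_two_value_formula(self):
        assert harmonic_mean_p([0.01, 0.1]) == pytest.approx(2 / 110.0)

    def test_single_value_identity(self):
        assert harmonic_mean_p([0.37]) == pytest.approx(0.37)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            harmonic_mean_p([0.1, 0.0])
        with pytest.raises(ValueError):
            harmonic_mean_p([])

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=10))
    def test_bounded_by_min_and_max(self, ps):
        hm = harmonic_mean_p(ps)
        assert min(ps) - 1e-12 <= hm <= max(ps) + 1e-12


class TestResponderRule:
    @pytest.mark.parametrize(
        "mean_auc,hm_p,expected",
        [(0.62, 0.03, True), (0.75, 0.2, False), (0.59, 0.001, False),
         (0.6, 0.049, True)],
    )
    def test_threshold_and_alpha(self, mean_auc, hm_p, expected):
        w = WindowSummary(30, mean_auc, hm_p, 10, 10,
                          bool(mean_auc >= 0.6 and hm_p < 0.05))
        s = PatientSummary({30: w})
        flags = classify_responder(s)
        assert flags[30] is expected and flags["any"] is expected

    def test_any_window_makes_patient_responder(self):
        s = PatientSummary({
            30: WindowSummary(30, 0.5, 0.9, 10, 5, False),
            15: WindowSummary(15, 0.7, 0.01, 10, 9, True),
        })
        assert s.responder is True


class TestSummarizePatient:
    def test_nonconverged_assigned_chance_and_p_one(self):
        reps = [
            RepeatResult(30, r, _model(np.zeros(16)), 0.9,
                         np.full(10, 0.5), np.r_[np.zeros(7), np.ones(3)])
            for r in range(10)
        ]
        s = summarize_patient(reps, n_perm=100, seed=0)
        w = s.windows[30]
        assert w.mean_auc == 0.5 and w.hm_p == 1.0
        assert w.n_converged == 0 and not w.responder


class TestFeatureFrequency:
    def test_counts_nonzero_fraction(self):
        coef_on = np.zeros(16)
        coef_on[3] = 1.0
        models = [_model(coef_on)] * 7 + [_model(np.r_[1.0, np.zeros(15)])] * 3
        df = feature_frequency(models).set_index("feature")
        assert df.loc["Q1-SOZ", "frequency"] == pytest.approx(0.7)
        assert df.loc["MEAN-SOZ", "frequency"] == pytest.approx(0.3)

    def test_nonconverged_excluded_from_denominator(self):
        coef_on = np.zeros(16)
        coef_on[0] = 2.0
        models = [_model(coef_on)] * 4 + [_model(np.zeros(16))] * 6
        df = feature_frequency(models).set_index("feature")
        assert df.loc["MEAN-SOZ", "frequency"] == pytest.approx(1.0)

    def test_no_converged_models_warns_empty(self):
        with pytest.warns(UserWarning, match="no converged"):
            df = feature_frequency([_model(np.zeros(16))])
        assert df.empty


class TestResponderProportionCI:
    def test_10_of_27_whole_percent(self):
        assert responder_proportion_ci(10, 27) == (19, 55)

    def test_zero_responders_clipped_at_zero(self):
        lo, hi = responder_proportion_ci(0, 27)
        assert lo == 0

    def test_5_of_10(self):
        assert responder_proportion_ci(5, 10) == (19, 81)

    def test_method_flag_wilson(self):
        lo, hi = responder_proportion_ci(10, 27, method="wilson")
        assert 0 <= lo < hi <= 100

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            responder_proportion_ci(5, 0)
        with pytest.raises(ValueError):
            responder_proportion_ci(11, 10)
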