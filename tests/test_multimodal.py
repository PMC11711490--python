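"""Multimodal integration, screening arithmetic, LOO-CV harness."""

import numpy as np
import pytest

from ctdetect.multimodal import (
    combine_modalities,
    loo_cv,
    origin_features,
    rank_auc,
    score_change,
    screening_performance,
)
from ctdetect.refstats import ModalityScore


def ms(z, p, modality="cna", k=1):
    return ModalityScore(modality, k, z, p)


class TestCombine:
    def test_single_strong_modality(self):
        res = combine_modalities([ms(3.0, 0.0013), ms(0.0, 0.5, "snv", 0),
                                  ms(0.0, 0.5, "meth", 0)])
        assert res.z == pytest.approx(3.0 / np.sqrt(3.0), abs=1e-4)
        assert res.p == pytest.approx(0.0416, abs=1e-3)
        assert res.call

    def test_all_neutral_is_negative(self):
        res = combine_modalities([ms(0.0, 0.5, m, 0) for m in ("cna", "snv", "meth")])
        assert (res.z, res.p, res.call) == (0.0, 0.5, False)

    def test_zero_weight_modalities_drop_out(self):
        one = combine_modalities([ms(2.5, 0.0062)])
        three = combine_modalities(
            [ms(2.5, 0.0062), ms(9.9, 1e-9, "snv"), ms(-2.0, 0.98, "meth")],
            weights=[1.0, 0.0, 0.0],
        )
        assert three.z == pytest.approx(one.z)
        assert three.p == pytest.approx(one.p)

    def test_stouffer_monotone_in_modality_strength(self):
        base = combine_modalities([ms(1.0, 0.159), ms(1.0, 0.159, "snv")])
        better = combine_modalities([ms(2.0, 0.023), ms(1.0, 0.159, "snv")])
        assert better.p < base.p

    def test_fisher_and_stouffer_agree_on_concordant_calls(self):
        scores = [ms(3.1, 0.001), ms(2.6, 0.005, "snv"), ms(2.3, 0.01, "meth")]
        assert combine_modalities(scores, method="stouffer").call
        assert combine_modalities(scores, method="fisher").call

    def test_empty_refused(self):
        with pytest.raises(ValueError):
            combine_modalities([])


class TestScreening:
    def test_symptomatic_cohort_npv(self):
        sp = screening_performance(0.852, 0.888, 0.067)
        assert sp.npv == pytest.approx(0.988, abs=5e-4)

    def test_primary_care_prevalence(self):
        sp = screening_performance(0.852, 0.888, 0.03)
        assert sp.npv == pytest.approx(0.995, abs=5e-4)
        assert sp.post_test_negative == pytest.approx(0.005, abs=5e-4)

    def test_perfect_sensitivity_perfect_npv(self):
        assert screening_performance(1.0, 0.5, 0.3).npv == 1.0

    def test_matches_brute_force_contingency(self):
        # build the 2x2 table explicitly on a grid and compare
        n = 1_000_000
        for sens in (0.6, 0.852, 0.99):
            for spec in (0.7, 0.888):
                for prev in (0.01, 0.067, 0.4):
                    tp = sens * prev * n
                    fn = (1 - sens) * prev * n
                    tn = spec * (1 - prev) * n
                    fp = (1 - spec) * (1 - prev) * n
                    sp = screening_performance(sens, spec, prev)
                    assert sp.npv == pytest.approx(tn / (tn + fn), rel=1e-12)
                    assert sp.ppv == pytest.approx(tp / (tp + fp), rel=1e-12)
                    assert sp.post_test_negative == pytest.approx(fn / (tn + fn), rel=1e-9)

    def test_degenerate_refused(self):
        with pytest.raises(ValueError):
            screening_performance(1.0, 0.0, 1.0)


class TestScoreChange:
    def test_printed_tracking_example(self):
        assert score_change(16.86, 4.34) == pytest.approx(74.26, abs=0.01)

    def test_no_change_and_full_clearance(self):
        assert score_change(10.0, 10.0) == 0.0
        assert score_change(10.0, 0.0) == 100.0

    def test_nonpositive_pre_refused(self):
        with pytest.raises(ValueError):
            score_change(0.0, 1.0)


class TestOriginFeatures:
    def test_concatenation_length_and_order(self):
        arms = [f"a{i}" for i in range(39)]
        markers = [f"m{i}" for i in range(377)]
        cov = {a: 0.0 for a in arms}
        bur = {a: 0.0 for a in arms}
        mel = {m: -4.0 for m in markers}
        vec, names = origin_features(cov, bur, mel, arms, markers)
        assert len(vec) == len(names) == 455
        assert names[0] == "cov:a0" and names[39] == "snv:a0" and names[78] == "meth:m0"

    def test_permuting_input_maps_changes_nothing(self):
        arms, markers = ["a", "b"], ["x"]
        v1, _ = origin_features({"a": 1, "b": 2}, {"a": 3, "b": 4}, {"x": 5}, arms, markers)
        v2, _ = origin_features({"b": 2, "a": 1}, {"b": 4, "a": 3}, {"x": 5}, arms, markers)
        assert np.array_equal(v1, v2)

    def test_mismatched_universe_refused(self):
        with pytest.raises(ValueError, match="mismatch"):
            origin_features({"a": 1}, {"a": 1}, {}, ["a"], ["x"])


class TestRankAuc:
    def test_brute_force_pairs(self):
        # cases {3, 1}, controls {2, 0}: 3 of 4 pairs won
        assert rank_auc(np.array([3, 1, 2, 0]), np.array([1, 1, 0, 0])) == 0.75

    def test_disjoint_ranges(self):
        assert rank_auc(np.array([5, 6, 1, 2]), np.array([1, 1, 0, 0])) == 1.0

    def test_ties_get_half_credit(self):
        assert rank_auc(np.array([1.0, 1.0]), np.array([1, 0])) == 0.5


class TestLooCv:
    def test_case_weights_proportionality(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(3, 1, (36, 2)), rng.normal(-3, 1, (4, 2))])
        y = np.array([1] * 36 + [0] * 4)
        rep = loo_cv(X, y, model="logistic")
        assert rep.case_weights == {"0": 9.0, "1": 1.0}

    def test_perfect_separation_perfect_metrics(self):
        z = np.vstack([np.full((10, 3), 4.0), np.full((10, 3), 0.0)])
        y = np.array([1] * 10 + [0] * 10)
        rep = loo_cv(z, y, model="stouffer")
        assert rep.auc == 1.0
        assert rep.sensitivity == 1.0
        assert rep.specificity == 1.0

    def test_one_prediction_per_subject(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 2))
        y = np.array([1] * 8 + [0] * 7)
        rep = loo_cv(X, y, model="fisher")
        assert len(rep.predictions) == 15

    def test_predictions_invariant_to_subject_order(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(1, 1, (8, 2)), rng.normal(-1, 1, (8, 2))])
        y = np.array([1] * 8 + [0] * 8)
        perm = rng.permutation(16)
        a = loo_cv(X, y, model="logistic", seed=0)
        b = loo_cv(X[perm], y[perm], model="logistic", seed=0)
        got_a = dict(zip(range(16), a.predictions["predicted"]))
        got_b = dict(zip(perm, b.predictions["predicted"]))
        assert all(got_a[i] == got_b[i] for i in range(16))

    def test_singleton_class_excluded_multiclass(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(9, 2))
        X[:4] += 4
        y = np.array(["crc"] * 4 + ["renal"] * 4 + ["breast"])
        with pytest.warns(UserWarning, match="single-member"):
            rep = loo_cv(X, y, model="rf")
        assert len(rep.predictions) == 8
        assert rep.confusion is not None
        assert rep.balanced_accuracy is not None

    def test_single_class_refused(self):
        with pytest.raises(ValueError):
            loo_cv(np.zeros((4, 2)), np.ones(4), model="logistic")
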