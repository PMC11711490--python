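"""Reference-cohort scoring and p-value combination."""

import math

import numpy as np
import pytest
from scipy import stats as sstats

from ctdetect.refstats import (
    ModalityScore,
    bh_adjust,
    compute_reference_stats,
    fisher,
    modality_score,
    score_features,
    stouffer,
)


def brute_force_bh(p):
    """Step-up BH by direct enumeration of the definition."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q = [0.0] * n
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * n / rank)
        q[i] = val
        prev = val
    return q


class TestScoreFeatures:
    def test_identity_sample_scores_zero(self):
        ref = [{"a": 1.0, "b": 2.0}, {"a": 3.0, "b": 0.0}, {"a": 2.0, "b": 1.0}]
        m = {k: np.mean([r[k] for r in ref]) for k in "ab"}
        out = score_features(m, ref)
        assert np.allclose(out["z"], 0.0)
        assert np.allclose(out["p"], 1.0)
        assert not out["significant"].any()

    def test_closed_form_t_example(self):
        # sample 2 vs reference {-1, 0, 1}: z = 2, t = 2/sqrt(4/3),
        # two-sided p from the df=2 closed form P(T<=t) = 1/2 + t/(2 sqrt(t^2+2))
        out = score_features({"a": 2.0}, [{"a": -1.0}, {"a": 0.0}, {"a": 1.0}])
        t = 2.0 / math.sqrt(4.0 / 3.0)
        p_expected = 2.0 * (1.0 - (0.5 + t / (2.0 * math.sqrt(t**2 + 2.0))))
        assert out["z"].iloc[0] == pytest.approx(2.0)
        assert out["t"].iloc[0] == pytest.approx(1.7321, abs=1e-4)
        assert out["p"].iloc[0] == pytest.approx(p_expected, rel=1e-12)
        assert out["p"].iloc[0] == pytest.approx(0.2254, abs=1e-4)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n_ref = int(rng.integers(3, 10))
            ref = [
                {f"f{j}": float(rng.normal()) for j in range(5)} for _ in range(n_ref)
            ]
            sample = {f"f{j}": float(rng.normal()) for j in range(5)}
            out = score_features(sample, ref, sided="two").set_index("feature_id")
            for j in range(5):
                vals = [r[f"f{j}"] for r in ref]
                m, s = np.mean(vals), np.std(vals, ddof=1)
                z = (sample[f"f{j}"] - m) / s
                t = z / math.sqrt(1 + 1 / n_ref)
                p = 2 * sstats.t.sf(abs(t), n_ref - 1)
                row = out.loc[f"f{j}"]
                assert row["z"] == pytest.approx(z, rel=1e-10)
                assert row["t"] == pytest.approx(t, rel=1e-10)
                assert row["p"] == pytest.approx(p, rel=1e-10)

    def test_upper_tailed_direction(self):
        out = score_features({"a": 5.0}, [{"a": 0.0}, {"a": 1.0}, {"a": 2.0}],
                             sided="upper")
        assert (out["direction"] == "increase").all()
        assert out["p"].iloc[0] < 0.5

    def test_zero_variance_feature_excluded_with_warning(self):
        ref = [{"a": 1.0, "b": 5.0}, {"a": 2.0, "b": 5.0}, {"a": 3.0, "b": 5.0}]
        with pytest.warns(UserWarning, match="zero reference variance"):
            out = score_features({"a": 2.0, "b": 7.0}, ref)
        assert list(out["feature_id"]) == ["a"]

    def test_all_zero_variance_gives_empty_result(self):
        ref = [{"a": 5.0}, {"a": 5.0}]
        with pytest.warns(UserWarning):
            out = score_features({"a": 7.0}, ref)
        assert out.empty

    def test_refusals(self):
        with pytest.raises(ValueError, match=">= 2"):
            score_features({"a": 1.0}, [{"a": 1.0}])
        with pytest.raises(ValueError, match="empty"):
            score_features({}, [{"a": 1.0}, {"a": 2.0}])
        with pytest.raises(ValueError):
            compute_reference_stats([{"a": 1.0}, {"b": 2.0}], features=["a"])


class TestBH:
    def test_single_value_unchanged(self):
        assert bh_adjust([0.05]) == pytest.approx([0.05])

    def test_equal_rank_scaling(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_monotonicity_enforcement(self):
        assert bh_adjust([0.01, 0.005]) == pytest.approx([0.01, 0.01])

    def test_against_brute_force_and_invariants(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(1, 7))
            p = rng.uniform(1e-6, 1.0, n)
            q = bh_adjust(p)
            assert q == pytest.approx(brute_force_bh(p), rel=1e-12)
            assert np.all(q >= p - 1e-15)
            perm = rng.permutation(n)
            assert q[perm] == pytest.approx(bh_adjust(p[perm]), rel=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([1.5])


class TestStouffer:
    def test_neutral_single_p(self):
        z, p = stouffer([0.5])
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(0.5, abs=1e-12)

    def test_two_identical_ps(self):
        z, p = stouffer([0.05, 0.05])
        assert z == pytest.approx(2.3262, abs=1e-4)
        assert p == pytest.approx(0.0100, abs=1e-4)

    def test_zero_weight_modality_drops_out(self):
        z1, p1 = stouffer([0.01, 0.9], weights=[1.0, 0.0])
        z2, p2 = stouffer([0.01])
        assert (z1, p1) == pytest.approx((z2, p2))

    def test_replication_scales_z_by_sqrt_m(self):
        z1, _ = stouffer([0.05])
        prev_p = 1.0
        for m in range(1, 6):
            z, p = stouffer([0.05] * m)
            assert z == pytest.approx(z1 * math.sqrt(m), rel=1e-10)
            assert p < prev_p
            prev_p = p

    def test_refusals(self):
        with pytest.raises(ValueError):
            stouffer([])
        with pytest.raises(ValueError):
            stouffer([0.1, 0.2], weights=[0.0, 0.0])


class TestFisher:
    def test_all_ones(self):
        s, p = fisher([1.0, 1.0, 1.0])
        assert s == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_three_small_ps(self):
        s, p = fisher([0.05] * 3)
        assert s == pytest.approx(17.974, abs=1e-3)
        assert p == pytest.approx(0.0063, abs=1e-4)

    def test_single_p_is_identity(self):
        for pv in (0.01, 0.2, 0.7):
            _, p = fisher([pv])
            assert p == pytest.approx(pv, rel=1e-10)


class TestModalityScore:
    def test_no_significant_features_is_neutral(self):
        scores = score_features(
            {"a": 0.5, "b": -0.2},
            [{"a": 0.0, "b": 0.0}, {"a": 1.0, "b": 1.0}, {"a": 0.5, "b": -1.0}],
        )
        ms = modality_score(scores)
        assert (ms.k_significant, ms.z, ms.p) == (0, 0.0, 0.5)

    def test_single_significant_feature_passes_through(self):
        import pandas as pd

        scores = pd.DataFrame(
            {
                "feature_id": ["a", "b"],
                "y": [9.0, 0.0], "z": [9.0, 0.0], "t": [8.5, 0.0],
                "p": [0.001, 0.8], "q": [0.002, 0.8],
                "significant": [True, False], "direction": ["gain", "gain"],
            }
        )
        ms = modality_score(scores)
        assert ms.k_significant == 1
        assert ms.z == pytest.approx(3.0902, abs=1e-4)
        assert ms.p == pytest.approx(0.001, rel=1e-6)

    def test_reference_sample_scored_against_rest_is_neutral(self):
        # leave-one-out over a homogeneous cohort: integrated scores all zero
        rng = np.random.default_rng(5)
        cohort = [{f"f{j}": float(rng.normal()) for j in range(6)} for _ in range(9)]
        zs = []
        for i, sample in enumerate(cohort):
            rest = cohort[:i] + cohort[i + 1 :]
            ms = modality_score(score_features(sample, rest))
            zs.append(ms.z)
        assert zs == [0.0] * 9

    def test_p_bounded_when_selected_ps_small(self):
        rng = np.random.default_rng(9)
        import pandas as pd

        for _ in range(50):
            k = int(rng.integers(1, 6))
            p = rng.uniform(1e-6, 0.49, k)
            scores = pd.DataFrame(
                {"feature_id": [f"f{i}" for i in range(k)], "y": 0.0, "z": 0.0,
                 "t": 0.0, "p": p, "q": np.full(k, 0.01),
                 "significant": True, "direction": "gain"}
            )
            ms = modality_score(scores)
            assert 0.0 < ms.p <= 0.5
            assert ms.z > 0.0

    def test_roundtrip_json(self):
        ms = ModalityScore("cna", 3, 2.5, 0.006)
        assert ModalityScore.from_json(ms.to_json()) == ms
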