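"""Coverage binning, debiasing, panel denoising and arm aggregation."""

import numpy as np
import pandas as pd
import pytest

import ctdetect as ct
from ctdetect.coverage import (
    build_noise_basis,
    counts_to_bins,
    denoise_and_smooth,
    extract_binned_coverage,
    make_bins,
    normalize_and_debias,
)

CHROMS = {"chr1": 10_000}


def aln(chrom="chr1", start=100, end=250, mapq=60, flags=0x2):
    return (chrom, start, end, mapq, flags)


class TestExtraction:
    def test_two_reads_in_one_bin(self):
        bins = extract_binned_coverage([aln(), aln(start=300, end=400)], CHROMS)
        assert bins["raw_count"].iloc[0] == 2
        assert bins["raw_count"].sum() == 2

    def test_low_mapq_not_counted(self):
        bins = extract_binned_coverage([aln(mapq=20)], CHROMS)
        assert bins["raw_count"].sum() == 0

    def test_mapq_threshold_is_strict(self):
        bins = extract_binned_coverage([aln(mapq=30), aln(mapq=31)], CHROMS)
        assert bins["raw_count"].sum() == 1

    def test_improper_pair_and_duplicate_excluded(self):
        bins = extract_binned_coverage(
            [aln(flags=0x0), aln(flags=0x2 | 0x400)], CHROMS
        )
        assert bins["raw_count"].sum() == 0

    def test_read_spanning_two_bins_increments_both(self):
        bins = extract_binned_coverage([aln(start=900, end=1100)], CHROMS)
        assert bins["raw_count"].iloc[0] == 1
        assert bins["raw_count"].iloc[1] == 1

    def test_blacklist_bin_masked(self):
        bl = pd.DataFrame([{"chrom": "chr1", "start": 1500, "end": 1600}])
        bins = extract_binned_coverage([aln()], CHROMS, blacklist=bl)
        assert bool(bins["masked"].iloc[1])
        assert not bins["masked"].iloc[0]

    def test_unknown_chromosome_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="unknown chromosomes"):
            bins = extract_binned_coverage([aln(chrom="chrZ"), aln()], CHROMS)
        assert bins["raw_count"].sum() == 1


def bins_from_counts(counts, gc=None, mp=None):
    n = len(counts)
    df = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n) * 1000,
            "end": (np.arange(n) + 1) * 1000,
            "raw_count": counts,
            "gc": 0.5 if gc is None else gc,
            "mappability": 1.0 if mp is None else mp,
            "masked": False,
        }
    )
    return df


class TestNormalizeDebias:
    def test_constant_counts_give_zero_signal(self):
        track = normalize_and_debias(bins_from_counts([7] * 50))
        assert np.allclose(track.y, 0.0, atol=1e-12)

    def test_log2_of_median_ratio(self):
        track = normalize_and_debias(bins_from_counts([100, 200, 400]), use_gam=False)
        # identical covariates: debias subtracts a constant; re-centering by the
        # mean leaves log2 ratios {-1,0,1} shifted by their mean 0
        assert track.y == pytest.approx([-1.0, 0.0, 1.0], abs=1e-9)

    def test_gc_driven_counts_are_decorrelated(self):
        rng = np.random.default_rng(3)
        n = 4000
        gc = np.clip(0.5 + 0.1 * np.sin(np.linspace(0, 20, n)) + rng.normal(0, 0.02, n), 0.3, 0.7)
        counts = rng.poisson(100 * 2.0 ** (1.5 * (gc - 0.5)))
        track = normalize_and_debias(bins_from_counts(counts, gc=gc))
        ok = track.unmasked
        r = np.corrcoef(track.y[ok], gc[ok])[0, 1]
        assert abs(r) < 0.05

    def test_zero_median_refused(self):
        with pytest.raises(ValueError):
            normalize_and_debias(bins_from_counts([0] * 10))


class TestNoiseBasis:
    def _track(self, y):
        bins = bins_from_counts([1] * len(y))
        return ct.CoverageTrack(bins=bins, y=np.asarray(y, float), stage="debiased")

    def test_single_track_spans_itself(self):
        v = np.array([1.0, 2.0, 2.0, -1.0])
        basis = build_noise_basis([self._track(v)])
        u = basis.U[:, 0]
        assert np.allclose(np.abs(u), np.abs(v / np.linalg.norm(v)))

    def test_orthonormal_and_exact_reconstruction(self):
        rng = np.random.default_rng(1)
        tracks = [self._track(rng.normal(size=200)) for _ in range(6)]
        basis = build_noise_basis(tracks)
        gram = basis.U.T @ basis.U
        assert np.abs(gram - np.eye(6)).max() < 1e-8
        for t in tracks:
            proj = basis.U @ (basis.U.T @ t.y)
            assert np.allclose(proj, t.y, atol=1e-10)

    def test_inconsistent_grids_refused(self):
        t1 = self._track(np.ones(5))
        t2 = ct.CoverageTrack(
            bins=bins_from_counts([1] * 6), y=np.ones(6), stage="debiased"
        )
        with pytest.raises(ValueError, match="inconsistent"):
            build_noise_basis([t1, t2])


class TestDenoiseSmooth:
    def test_in_span_signal_removed(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=3000)
        bins = bins_from_counts([1] * 3000)
        panel = ct.CoverageTrack(bins=bins, y=v, stage="debiased")
        basis = build_noise_basis([panel])
        out = denoise_and_smooth(
            ct.CoverageTrack(bins=bins, y=2.5 * v, stage="debiased"), basis
        )
        assert np.abs(out.y).max() < 1e-6

    def test_cubic_orthogonal_to_panel_unchanged(self):
        n = 3000
        x = np.linspace(-1, 1, n)
        cubic = 0.3 * x**3 - 0.2 * x
        rng = np.random.default_rng(4)
        v = rng.normal(size=n)
        v -= (v @ cubic) / (cubic @ cubic) * cubic  # orthogonalise
        bins = bins_from_counts([1] * n)
        basis = build_noise_basis([ct.CoverageTrack(bins=bins, y=v, stage="debiased")])
        out = denoise_and_smooth(
            ct.CoverageTrack(bins=bins, y=cubic.copy(), stage="debiased"),
            basis, sg_window_bins=501,
        )
        # order-3 Savitzky-Golay reproduces cubics; median-centering shifts by
        # the (tiny) median of the cubic itself
        expected = cubic - np.median(cubic)
        assert np.abs(out.y - expected).max() < 1e-6

    def test_white_noise_variance_reduced(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=5000)
        bins = bins_from_counts([1] * 5000)
        out = denoise_and_smooth(
            ct.CoverageTrack(bins=bins, y=y.copy(), stage="smoothed"), basis=None
        )
        assert out.y.var() < y.var()

    def test_svd_subtraction_idempotent_and_orthogonal(self):
        rng = np.random.default_rng(6)
        bins = bins_from_counts([1] * 400)
        panel = [
            ct.CoverageTrack(bins=bins, y=rng.normal(size=400), stage="debiased")
            for _ in range(4)
        ]
        basis = build_noise_basis(panel)
        y = rng.normal(size=400)
        once = y - basis.U @ (basis.U.T @ y)
        twice = once - basis.U @ (basis.U.T @ once)
        assert np.abs(once - twice).max() < 1e-10
        assert np.abs(basis.U.T @ once).max() < 1e-8

    def test_output_median_centred(self):
        rng = np.random.default_rng(7)
        bins = bins_from_counts([1] * 4000)
        out = denoise_and_smooth(
            ct.CoverageTrack(bins=bins, y=rng.normal(1.3, 1, 4000), stage="debiased"),
            basis=None,
        )
        assert abs(np.median(out.y[out.unmasked])) < 1e-9

    def test_short_chromosome_shrinks_window(self):
        bins = bins_from_counts([1] * 50)
        with pytest.warns(UserWarning, match="window shrunk"):
            denoise_and_smooth(
                ct.CoverageTrack(bins=bins, y=np.zeros(50), stage="debiased"),
                basis=None,
            )


class TestAggregateArms:
    ARMS = pd.DataFrame(
        [{"chrom": "chr1", "start": 0, "end": 3000, "arm_id": "chr1p"}]
    )

    def _track(self, y, masked=None):
        n = len(y)
        bins = bins_from_counts([1] * n)
        if masked is not None:
            bins["masked"] = masked
        yy = np.asarray(y, float)
        return ct.CoverageTrack(bins=bins, y=yy, stage="smoothed")

    def test_mean_of_arm_bins(self):
        out = ct.aggregate_arms(self._track([0.1, 0.2, 0.3]), self.ARMS, min_bins=1)
        assert out["value"].iloc[0] == pytest.approx(0.2)

    def test_masked_bin_excluded(self):
        out = ct.aggregate_arms(
            self._track([0.1, 9.9, 0.3], masked=[False, True, False]),
            self.ARMS, min_bins=1,
        )
        assert out["value"].iloc[0] == pytest.approx(0.2)

    def test_zero_track_zero_aggregates(self):
        out = ct.aggregate_arms(self._track([0.0] * 3), self.ARMS, min_bins=1)
        assert out["value"].iloc[0] == 0.0

    def test_underpopulated_arm_dropped(self):
        with pytest.warns(UserWarning, match="dropped"):
            out = ct.aggregate_arms(self._track([0.1] * 3), self.ARMS, min_bins=100)
        assert out.empty
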