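"""Binned coverage extraction, debiasing, panel-of-normals denoising, smoothing.

The copy-number signal travels through the stages

    raw counts -> median-log2 normalisation -> GC/mappability debiasing
    -> SVD background subtraction -> Savitzky-Golay smoothing
    -> arm aggregation

on 1 kb non-overlapping bins. Bins hit by blacklist regions, with mappability
below 0.5 or GC outside a configured window are masked and carry no signal
downstream. The noise basis is the left-singular-vector span of a panel of
identically pre-processed non-cancer samples; a sample's projection onto that
span (U U^T y) is treated as shared systematic background and subtracted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.signal import savgol_filter

__all__ = [
    "BIN_SIZE",
    "CoverageTrack",
    "NoiseBasis",
    "make_bins",
    "extract_binned_coverage",
    "normalize_and_debias",
    "build_noise_basis",
    "denoise_and_smooth",
    "aggregate_arms",
]

BIN_SIZE = 1000

# SAM flag bits
_FLAG_PROPER_PAIR = 0x2
_FLAG_UNMAPPED = 0x4
_FLAG_SECONDARY = 0x100
_FLAG_DUP = 0x400
_FLAG_SUPPLEMENTARY = 0x800

_BIN_COLS = ["chrom", "start", "end", "raw_count", "gc", "mappability", "masked"]


@dataclass
class CoverageTrack:
    """Per-bin normalised log2 coverage at a named pipeline stage.

    ``bins`` is the bin table (chrom, start, end, raw_count, gc,
    mappability, masked); ``y`` holds the signal, NaN on masked bins.
    """

    bins: pd.DataFrame
    y: np.ndarray
    stage: str = "raw"

    @property
    def unmasked(self) -> np.ndarray:
        return ~self.bins["masked"].to_numpy()

    def to_frame(self) -> pd.DataFrame:
        out = self.bins[["chrom", "start", "end"]].copy()
        out["y"] = self.y
        out["masked"] = self.bins["masked"].to_numpy()
        out["stage"] = self.stage
        return out


@dataclass
class NoiseBasis:
    """Orthonormal basis of the noise-panel span over unmasked bins."""

    U: np.ndarray  # (n_unmasked, m)
    bin_index: np.ndarray  # positions of the unmasked bins in the bin table
    panel_ids: list[str] = field(default_factory=list)


def make_bins(chrom_sizes: dict[str, int], bin_size: int = BIN_SIZE) -> pd.DataFrame:
    """Non-overlapping genome bins; the last bin of a chromosome may be short."""
    rows = []
    for chrom, size in chrom_sizes.items():
        starts = np.arange(0, size, bin_size)
        ends = np.minimum(starts + bin_size, size)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    bins = pd.concat(rows, ignore_index=True)
    bins["raw_count"] = 0
    bins["gc"] = np.nan
    bins["mappability"] = np.nan
    bins["masked"] = False
    return bins


def _annotate_per_bin(bins: pd.DataFrame, track: pd.DataFrame, col: str) -> None:
    """Copy a per-bin bedGraph-like table (chrom,start,end,value) onto bins."""
    key = track.set_index(["chrom", "start"])[track.columns[3]]
    idx = pd.MultiIndex.from_arrays([bins["chrom"], bins["start"]])
    bins[col] = key.reindex(idx).to_numpy()


def extract_binned_coverage(
    alignments,
    chrom_sizes: dict[str, int],
    blacklist: pd.DataFrame | None = None,
    gc_track: pd.DataFrame | None = None,
    map_track: pd.DataFrame | None = None,
    min_mapq: int = 30,
    gc_range: tuple[float, float] = (0.3, 0.7),
    min_mappability: float = 0.5,
    bin_size: int = BIN_SIZE,
) -> pd.DataFrame:
    """Count qualifying alignments per bin and apply masking.

    ``alignments`` yields ``(chrom, start, end, mapq, flags)`` tuples
    (0-based half-open). Only properly paired, non-duplicate, primary
    alignments with MAPQ > ``min_mapq`` are counted; a read overlapping two
    bins increments both. Bins overlapping any blacklist interval, with
    mappability < ``min_mappability`` or GC outside ``gc_range`` are masked.
    """
    bins = make_bins(chrom_sizes, bin_size)
    counts: dict[str, np.ndarray] = {
        c: np.zeros(int(np.ceil(s / bin_size)), dtype=np.int64)
        for c, s in chrom_sizes.items()
    }
    unknown: set[str] = set()
    for chrom, start, end, mapq, flags in alignments:
        if chrom not in counts:
            unknown.add(chrom)
            continue
        if mapq <= min_mapq:
            continue
        if not (flags & _FLAG_PROPER_PAIR):
            continue
        if flags & (_FLAG_DUP | _FLAG_UNMAPPED | _FLAG_SECONDARY | _FLAG_SUPPLEMENTARY):
            continue
        arr = counts[chrom]
        b0 = start // bin_size
        b1 = (max(end, start + 1) - 1) // bin_size
        arr[b0 : min(b1, len(arr) - 1) + 1] += 1
    if unknown:
        warnings.warn(f"skipped alignments on unknown chromosomes: {sorted(unknown)}")

    per_chrom = [counts[c] for c in dict.fromkeys(bins["chrom"])]
    bins["raw_count"] = np.concatenate(per_chrom)

    if gc_track is not None:
        _annotate_per_bin(bins, gc_track, "gc")
    if map_track is not None:
        _annotate_per_bin(bins, map_track, "mappability")

    masked = np.zeros(len(bins), dtype=bool)
    if blacklist is not None and len(blacklist):
        trees: dict[str, IntervalTree] = {}
        for chrom, grp in blacklist.groupby("chrom"):
            trees[chrom] = IntervalTree.from_tuples(
                zip(grp["start"].astype(int), grp["end"].astype(int))
            )
        for i, (chrom, s, e) in enumerate(
            zip(bins["chrom"], bins["start"], bins["end"])
        ):
            t = trees.get(chrom)
            if t is not None and t.overlaps(int(s), int(e)):
                masked[i] = True
    gcv = bins["gc"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        masked |= np.where(
            np.isnan(gcv), False, (gcv < gc_range[0]) | (gcv > gc_range[1])
        )
    mp = bins["mappability"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        masked |= np.where(np.isnan(mp), False, mp < min_mappability)
    bins["masked"] = masked
    return bins


def counts_to_bins(
    counts: pd.DataFrame,
    gc_track: pd.DataFrame | None = None,
    map_track: pd.DataFrame | None = None,
    blacklist: pd.DataFrame | None = None,
    gc_range: tuple[float, float] = (0.3, 0.7),
    min_mappability: float = 0.5,
) -> pd.DataFrame:
    """Build the bin table from a precomputed 4-column (chrom,start,end,count)
    table instead of raw alignments, applying the same masking rules."""
    bins = counts.rename(columns={counts.columns[3]: "raw_count"}).copy()
    bins = bins[["chrom", "start", "end", "raw_count"]]
    bins["gc"] = np.nan
    bins["mappability"] = np.nan
    if gc_track is not None:
        _annotate_per_bin(bins, gc_track, "gc")
    if map_track is not None:
        _annotate_per_bin(bins, map_track, "mappability")
    masked = np.zeros(len(bins), dtype=bool)
    if blacklist is not None and len(blacklist):
        trees = {
            chrom: IntervalTree.from_tuples(
                zip(grp["start"].astype(int), grp["end"].astype(int))
            )
            for chrom, grp in blacklist.groupby("chrom")
        }
        for i, (chrom, s, e) in enumerate(
            zip(bins["chrom"], bins["start"], bins["end"])
        ):
            t = trees.get(chrom)
            if t is not None and t.overlaps(int(s), int(e)):
                masked[i] = True
    gcv = bins["gc"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        masked |= np.where(
            np.isnan(gcv), False, (gcv < gc_range[0]) | (gcv > gc_range[1])
        )
    mp = bins["mappability"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        masked |= np.where(np.isnan(mp), False, mp < min_mappability)
    bins["masked"] = masked
    return bins


def _gam_fit(y: np.ndarray, gc: np.ndarray, mp: np.ndarray) -> np.ndarray:
    """Additive smooth fit of y on (gc, mappability); returns fitted values.

    Penalised cubic B-splines per covariate; covariates with no spread are
    dropped from the design.
    """
    from statsmodels.gam.api import GLMGam, BSplines

    cols, dfs = [], []
    for v in (gc, mp):
        if np.nanstd(v) > 1e-12:
            cols.append(v)
            dfs.append(min(8, max(4, len(np.unique(v)) // 4)))
    if not cols:
        return np.zeros_like(y)
    X = np.column_stack(cols)
    bs = BSplines(X, df=dfs, degree=[3] * len(dfs))
    model = GLMGam(y, np.ones((len(y), 1)), smoother=bs, alpha=[1.0] * len(dfs))
    res = model.fit()
    return np.asarray(res.fittedvalues)


def _binned_median_fit(y: np.ndarray, gc: np.ndarray, mp: np.ndarray) -> np.ndarray:
    """Fallback debias: subtract per-decile medians of each covariate."""
    fit = np.zeros_like(y)
    resid = y.copy()
    for v in (gc, mp):
        if np.nanstd(v) <= 1e-12:
            continue
        qs = np.nanquantile(v, np.linspace(0, 1, 11))
        qs[0] -= 1e-9
        grp = np.digitize(v, qs[1:-1])
        med = np.zeros_like(y)
        for g in np.unique(grp):
            sel = grp == g
            med[sel] = np.median(resid[sel])
        fit += med
        resid = resid - med
    return fit


def normalize_and_debias(bins: pd.DataFrame, use_gam: bool = True) -> CoverageTrack:
    """Median-log2 normalisation followed by GC/mappability debiasing.

    y = log2(count / genome-wide median count) on unmasked bins; an additive
    smooth fit on (gc, mappability) is subtracted; the result is re-centred
    by subtracting its genome-wide mean. Unmasked bins with zero counts are
    masked here (no finite log-ratio exists for them).
    """
    bins = bins.copy()
    unmasked = ~bins["masked"].to_numpy()
    zero = unmasked & (bins["raw_count"].to_numpy() == 0)
    if zero.any():
        bins.loc[zero, "masked"] = True
        unmasked = ~bins["masked"].to_numpy()
    counts = bins["raw_count"].to_numpy(dtype=float)
    if not unmasked.any():
        raise ValueError("no unmasked bins with nonzero counts")
    med = np.median(counts[unmasked])
    if med == 0:
        raise ValueError("genome-wide median coverage is zero")
    y = np.full(len(bins), np.nan)
    y[unmasked] = np.log2(counts[unmasked] / med)

    gc = bins["gc"].to_numpy(dtype=float)[unmasked]
    mp = bins["mappability"].to_numpy(dtype=float)[unmasked]
    gc = np.where(np.isnan(gc), np.nanmedian(gc) if not np.all(np.isnan(gc)) else 0.5, gc)
    mp = np.where(np.isnan(mp), np.nanmedian(mp) if not np.all(np.isnan(mp)) else 1.0, mp)
    yu = y[unmasked]
    if np.nanstd(gc) > 1e-12 or np.nanstd(mp) > 1e-12:
        if use_gam:
            try:
                fit = _gam_fit(yu, gc, mp)
            except Exception as e:  # pragma: no cover - backstop
                warnings.warn(f"GAM debiasing failed ({e}); using binned-median fallback")
                fit = _binned_median_fit(yu, gc, mp)
        else:
            fit = _binned_median_fit(yu, gc, mp)
        yu = yu - fit
    yu = yu - yu.mean()
    y[unmasked] = yu
    return CoverageTrack(bins=bins, y=y, stage="debiased")


def build_noise_basis(panel_tracks: list[CoverageTrack]) -> NoiseBasis:
    """Left singular vectors of the noise-panel matrix over shared unmasked bins.

    All panel tracks must share the same bin grid; the intersection of their
    unmasked bins is used and recorded in ``bin_index``.
    """
    if not panel_tracks:
        raise ValueError("empty noise panel")
    ref = panel_tracks[0].bins[["chrom", "start", "end"]]
    for t in panel_tracks[1:]:
        if not ref.equals(t.bins[["chrom", "start", "end"]]):
            raise ValueError("noise-panel tracks have inconsistent bin grids")
    common = np.logical_and.reduce([t.unmasked for t in panel_tracks])
    if not common.any():
        raise ValueError("no unmasked bins shared across the noise panel")
    idx = np.flatnonzero(common)
    M = np.column_stack([t.y[idx] for t in panel_tracks])
    U, _, _ = np.linalg.svd(M, full_matrices=False)
    return NoiseBasis(U=U, bin_index=idx, panel_ids=[f"panel_{i}" for i in range(M.shape[1])])


def denoise_and_smooth(
    track: CoverageTrack,
    basis: NoiseBasis | None,
    sg_order: int = 3,
    sg_window_bins: int = 1001,
) -> CoverageTrack:
    """Subtract the panel-span background, smooth, and re-centre.

    y <- y - U U^T y on the basis' bin index; the result is Savitzky-Golay
    filtered per chromosome over the sequence of consecutive unmasked bins
    (masked bins spliced out, not interpolated), then the genome-wide median
    is subtracted. An even window is bumped to the next odd length; a
    chromosome shorter than the window uses the largest odd length that fits.
    """
    bins = track.bins
    y = track.y.copy()
    if basis is not None:
        sub = y[basis.bin_index]
        if np.isnan(sub).any():
            # restrict to bins unmasked in both sample and panel
            ok = ~np.isnan(sub)
            idx = basis.bin_index[ok]
            U = basis.U[ok]
        else:
            idx, U = basis.bin_index, basis.U
        y[idx] = y[idx] - U @ (U.T @ y[idx])
    if sg_window_bins % 2 == 0:
        sg_window_bins += 1
    unmasked = track.unmasked
    chroms = bins["chrom"].to_numpy()
    for chrom in dict.fromkeys(chroms):
        sel = np.flatnonzero((chroms == chrom) & unmasked)
        n = len(sel)
        if n == 0:
            continue
        win = sg_window_bins
        if n < win:
            win = n if n % 2 == 1 else n - 1
            warnings.warn(
                f"{chrom}: only {n} unmasked bins; Savitzky-Golay window shrunk to {win}"
            )
        if win <= sg_order:
            continue  # too short to smooth
        y[sel] = savgol_filter(y[sel], window_length=win, polyorder=sg_order)
    med = np.nanmedian(y[unmasked])
    y[unmasked] -= med
    return CoverageTrack(bins=bins, y=y, stage="smoothed")


def aggregate_arms(
    track: CoverageTrack, arms: pd.DataFrame, min_bins: int = 100
) -> pd.DataFrame:
    """Mean smoothed signal per chromosome arm.

    ``arms`` has columns (chrom, start, end, arm_id). A bin belongs to the
    arm containing its start. Arms with fewer than ``min_bins`` unmasked bins
    are dropped with a warning. Returns (arm_id, value, n_bins).
    """
    bins = track.bins
    unmasked = track.unmasked
    rows = []
    for _, arm in arms.iterrows():
        sel = (
            (bins["chrom"] == arm["chrom"]).to_numpy()
            & (bins["start"].to_numpy() >= arm["start"])
            & (bins["start"].to_numpy() < arm["end"])
            & unmasked
        )
        n = int(sel.sum())
        if n < max(min_bins, 1):
            warnings.warn(f"arm {arm['arm_id']}: {n} unmasked bins (< {min_bins}); dropped")
            continue
        rows.append({"arm_id": arm["arm_id"], "value": float(np.mean(track.y[sel])), "n_bins": n})
    return pd.DataFrame(rows, columns=["arm_id", "value", "n_bins"])
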