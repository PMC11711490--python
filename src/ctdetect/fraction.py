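"""ctDNA fraction estimation from the denoised coverage track.

Plasma cfDNA is a mixture of DNA from diploid normal cells and tumour cells
of average (not necessarily integer) segment ploidy c_k, so the expected
untransformed coverage x = 2^(y + 1) of a segment is

    E[x_k] = 2 (1 - rho) + rho * c_k,

where rho is the ctDNA fraction. With per-segment observed means m_k,
variances s_k^2 and supporting bin counts N_k, modelling
x_ki ~ Normal(2(1-rho) + rho c_k, s_k^2) under uniform priors
rho ~ U(0, 1) and c_k ~ U(0, c_max) yields conjugate conditional
posteriors (truncated to the prior supports):

    rho | c ~ N( sum_k N_k (m_k-2)(c_k-2)/s_k^2 / D, 1/D ),
               D = sum_k N_k (c_k-2)^2 / s_k^2
    c_k | rho ~ N( (m_k - 2(1-rho)) / rho, s_k^2 / (N_k rho^2) )

which are sampled alternately (Gibbs). Segmentation subsamples the smoothed
track every 1000 bins and recovers constant-mean pieces with binary
segmentation; adjacent segments less than 3 pooled standard deviations
apart are merged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri

from .coverage import CoverageTrack

__all__ = [
    "Segment",
    "FractionPosterior",
    "segment_coverage",
    "estimate_fraction",
    "sample_truncated_normal",
    "identifiability_bound",
]

VAR_FLOOR = 1e-6


@dataclass(frozen=True)
class Segment:
    """Per-segment statistics of the untransformed coverage x = 2^(y+1)."""

    index: int
    chrom: str
    n_bins: int  # N_k, supporting subsampled bins
    mean: float  # m_k
    var: float  # s_k^2, floored at VAR_FLOOR


@dataclass
class FractionPosterior:
    rho_mean: float
    rho_sd: float
    cbar: np.ndarray  # posterior means of c_k per segment
    chain: np.ndarray  # post-burn-in rho draws
    iters: int
    burn_in: int
    seed: int | None
    unidentifiable: bool = False


def sample_truncated_normal(
    rng: np.random.Generator,
    mu: np.ndarray | float,
    sd: np.ndarray | float,
    lo: float,
    hi: float,
) -> np.ndarray | float:
    """Inverse-CDF draw from Normal(mu, sd^2) truncated to [lo, hi]."""
    mu = np.asarray(mu, dtype=float)
    sd = np.asarray(sd, dtype=float)
    a = ndtr((lo - mu) / sd)
    b = ndtr((hi - mu) / sd)
    # when the window has essentially no mass, clamp to the nearer bound
    u = a + (b - a) * rng.uniform(size=mu.shape if mu.shape else None)
    u = np.clip(u, 1e-15, 1 - 1e-15)
    x = mu + sd * ndtri(u)
    return np.clip(x, lo, hi)


def _binary_segment(y: np.ndarray, penalty: float, min_size: int = 2) -> list[int]:
    """Recursive binary segmentation on a 1-D series.

    A split is accepted when it reduces the total within-segment sum of
    squares by more than ``penalty``. Returns sorted breakpoints (exclusive
    end indices of segments, excluding len(y)).
    """

    def sse(a: int, b: int) -> float:
        seg = y[a:b]
        return float(((seg - seg.mean()) ** 2).sum()) if b > a else 0.0

    breaks: list[int] = []

    def recurse(a: int, b: int) -> None:
        n = b - a
        if n < 2 * min_size:
            return
        total = sse(a, b)
        seg = y[a:b]
        cs = np.cumsum(seg)
        css = np.cumsum(seg**2)
        best_gain, best_split = 0.0, None
        for i in range(min_size, n - min_size + 1):
            left_ss = css[i - 1] - cs[i - 1] ** 2 / i
            right_n = n - i
            right_sum = cs[-1] - cs[i - 1]
            right_ss = (css[-1] - css[i - 1]) - right_sum**2 / right_n
            gain = total - (left_ss + right_ss)
            if gain > best_gain:
                best_gain, best_split = gain, i
        if best_split is not None and best_gain > penalty:
            recurse(a, a + best_split)
            breaks.append(a + best_split)
            recurse(a + best_split, b)

    recurse(0, len(y))
    return sorted(breaks)


def _merge_segments(
    y: np.ndarray, bounds: list[tuple[int, int]], merge_sd: float
) -> list[tuple[int, int]]:
    """Merge adjacent segments whose means differ by < merge_sd pooled SDs."""
    bounds = list(bounds)
    changed = True
    while changed and len(bounds) > 1:
        changed = False
        for i in range(len(bounds) - 1):
            a0, a1 = bounds[i]
            b0, b1 = bounds[i + 1]
            seg_a, seg_b = y[a0:a1], y[b0:b1]
            na, nb = len(seg_a), len(seg_b)
            pooled_var = (
                ((na - 1) * seg_a.var(ddof=1) if na > 1 else 0.0)
                + ((nb - 1) * seg_b.var(ddof=1) if nb > 1 else 0.0)
            ) / max(na + nb - 2, 1)
            pooled_sd = np.sqrt(pooled_var)
            diff = abs(seg_a.mean() - seg_b.mean())
            if pooled_sd == 0.0:
                mergeable = diff == 0.0
            else:
                mergeable = diff < merge_sd * pooled_sd
            if mergeable:
                bounds[i : i + 2] = [(a0, b1)]
                changed = True
                break
    return bounds


def segment_coverage(
    track: CoverageTrack,
    subsample_every: int = 1000,
    merge_sd: float = 3.0,
    min_size: int = 2,
) -> list[Segment]:
    """Piecewise-constant segmentation of the subsampled coverage signal.

    The unmasked smoothed signal is subsampled every ``subsample_every``
    bins per chromosome, segmented by binary segmentation with a
    robust-noise BIC-style penalty, and adjacent segments less than
    ``merge_sd`` pooled standard deviations apart are merged. Per-segment
    statistics (N_k, m_k, s_k^2) are computed on the untransformed coverage
    x = 2^(y + 1); variances are floored at 1e-6.
    """
    bins = track.bins
    unmasked = track.unmasked
    chroms = bins["chrom"].to_numpy()
    segments: list[Segment] = []
    idx = 0
    total_pts = 0
    for chrom in dict.fromkeys(chroms):
        sel = np.flatnonzero((chroms == chrom) & unmasked)
        ys = track.y[sel][::subsample_every]
        total_pts += len(ys)
        if len(ys) < min_size:
            continue
        # robust noise scale from first differences (breakpoint-insensitive)
        if len(ys) > 2:
            sigma2 = (np.median(np.abs(np.diff(ys))) / 0.6745) ** 2 / 2.0
        else:
            sigma2 = float(np.var(ys))
        penalty = max(3.0 * sigma2 * np.log(max(len(ys), 2)), 1e-12)
        breaks = _binary_segment(ys, penalty, min_size=min_size)
        edges = [0] + breaks + [len(ys)]
        bounds = [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
        bounds = _merge_segments(ys, bounds, merge_sd)
        for a, b in bounds:
            x = 2.0 ** (ys[a:b] + 1.0)
            if b - a < 2:
                continue
            segments.append(
                Segment(
                    index=idx,
                    chrom=chrom,
                    n_bins=b - a,
                    mean=float(x.mean()),
                    var=float(max(x.var(ddof=1), VAR_FLOOR)),
                )
            )
            idx += 1
    if total_pts < 2:
        raise ValueError("fewer than 2 subsampled points; cannot segment")
    return segments


def identifiability_bound(segments: list[Segment], c_max: float = 4.0) -> float:
    """Smallest rho for which every observed segment mean is attainable
    with c_k inside [0, c_max]: rho_min = max_k |m_k - 2| / max(2, c_max-2)."""
    dev = max(abs(s.mean - 2.0) for s in segments)
    return dev / max(2.0, c_max - 2.0)


def estimate_fraction(
    segments: list[Segment],
    iters: int = 10_000,
    burn_in: int = 5_000,
    c_max: float = 4.0,
    seed: int | None = None,
    fix_cbar: np.ndarray | None = None,
    aberration_tol: float = 0.05,
) -> FractionPosterior:
    """Gibbs posterior over (rho, c_k) given segment statistics.

    Draws alternate between the conditional for rho (truncated to [0, 1])
    and for each c_k (truncated to [0, c_max]). ``fix_cbar`` clamps the
    segment ploidies to known values, sampling rho only. A sample with no
    aberrant segment (all m_k within ``aberration_tol`` of 2) is flagged
    unidentifiable — the conditional for rho is then uninformative.
    """
    if not segments:
        raise ValueError("no segments")
    if not (0 < burn_in < iters):
        raise ValueError("need 0 < burn_in < iters")
    rng = np.random.default_rng(seed)
    m = np.array([s.mean for s in segments])
    v = np.array([s.var for s in segments])
    n = np.array([s.n_bins for s in segments], dtype=float)
    unident = bool(np.all(np.abs(m - 2.0) < aberration_tol))

    if fix_cbar is not None:
        c = np.asarray(fix_cbar, dtype=float).copy()
        if c.shape != m.shape:
            raise ValueError("fix_cbar must have one value per segment")
    else:
        c = np.full_like(m, 2.0)
    rho = float(rng.uniform(0.0, 1.0))

    rho_draws = np.empty(iters)
    c_draws = np.empty((iters, len(segments)))
    for it in range(iters):
        # rho | c
        d = float(np.sum(n * (c - 2.0) ** 2 / v))
        if d > 0:
            mu_rho = float(np.sum(n * (m - 2.0) * (c - 2.0) / v)) / d
            rho = float(
                sample_truncated_normal(rng, mu_rho, np.sqrt(1.0 / d), 0.0, 1.0)
            )
        else:  # all c_k at 2: likelihood flat in rho -> draw from the prior
            rho = float(rng.uniform(0.0, 1.0))
        # c_k | rho
        if fix_cbar is None:
            if rho > 1e-12:
                mu_c = (m - 2.0 * (1.0 - rho)) / rho
                sd_c = np.sqrt(v / (n * rho**2))
                c = np.asarray(
                    sample_truncated_normal(rng, mu_c, sd_c, 0.0, c_max)
                )
            else:
                c = rng.uniform(0.0, c_max, size=len(segments))
        rho_draws[it] = rho
        c_draws[it] = c

    chain = rho_draws[burn_in:]
    return FractionPosterior(
        rho_mean=float(chain.mean()),
        rho_sd=float(chain.std(ddof=1)),
        cbar=c_draws[burn_in:].mean(axis=0),
        chain=chain,
        iters=iters,
        burn_in=burn_in,
        seed=seed,
        unidentifiable=unident,
    )
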