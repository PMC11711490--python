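"""Reference-cohort scoring and p-value combination.

This is the statistical core shared by the three data modalities. A sample's
per-feature values (arm-aggregated coverage, arm log10 mutation burden, or
per-marker methylation logits) are compared against a small cohort of
non-cancer reference samples: for feature ``k`` with reference mean ``m_k``
and standard deviation ``s_k`` estimated from ``N`` reference samples,

    z_k = (y_k - m_k) / s_k
    t_k = z_k / sqrt(1 + 1/N)

where ``t_k`` follows a t distribution with ``N - 1`` degrees of freedom.
P-values are corrected per sample with Benjamini-Hochberg; the uncorrected
p-values of the significant (q < alpha) features are then combined into a
per-modality score with Stouffer's method.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr, ndtri
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ReferenceStats",
    "ModalityScore",
    "compute_reference_stats",
    "score_features",
    "bh_adjust",
    "stouffer",
    "fisher",
    "modality_score",
]

# clipping bounds keeping the probit transform finite
_P_LO = 1e-300
_P_HI = 1.0 - 1e-16

#: columns of the per-feature score table produced by :func:`score_features`
SCORE_COLUMNS = ["feature_id", "y", "z", "t", "p", "q", "significant", "direction"]


@dataclass(frozen=True)
class ReferenceStats:
    """Per-feature reference-cohort summary (mean, SD, cohort size)."""

    feature_id: str
    m: float
    s: float
    n: int
    excluded: bool = False  # s == 0: a degenerate reference conveys no scale


@dataclass(frozen=True)
class ModalityScore:
    """Integrated per-modality score.

    ``k_significant`` counts the features passing the q < alpha filter; their
    uncorrected p-values are Stouffer-combined into ``z`` with p = 1 - Phi(z).
    A sample with no significant features is neutral: z = 0, p = 0.5.
    """

    modality: str
    k_significant: int
    z: float
    p: float

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModalityScore":
        return cls(**json.loads(s))


def compute_reference_stats(
    reference: Sequence[Mapping[str, float]],
    features: Iterable[str] | None = None,
) -> list[ReferenceStats]:
    """Per-feature mean and (ddof=1) SD across the reference cohort.

    Parameters
    ----------
    reference
        One mapping feature -> value per reference sample; N = len(reference).
    features
        Restrict/force the feature universe; defaults to the keys of the
        first reference sample.
    """
    n = len(reference)
    if n < 2:
        raise ValueError(f"reference cohort must contain >= 2 samples, got {n}")
    if features is None:
        features = list(reference[0].keys())
    else:
        features = list(features)
    if not features:
        raise ValueError("empty feature set")
    out = []
    for f in features:
        try:
            vals = np.array([r[f] for r in reference], dtype=float)
        except KeyError as e:
            raise ValueError(f"feature {f!r} missing from a reference sample") from e
        m = float(vals.mean())
        s = float(vals.std(ddof=1))
        out.append(ReferenceStats(f, m, s, n, excluded=(s == 0.0)))
    return out


def score_features(
    sample_values: Mapping[str, float],
    reference: Sequence[Mapping[str, float]] | Sequence[ReferenceStats],
    alpha: float = 0.05,
    sided: str = "two",
) -> pd.DataFrame:
    """Score a sample's features against a reference cohort.

    Returns a DataFrame with columns ``feature_id, y, z, t, p, q,
    significant, direction``. Features whose reference SD is zero are
    excluded with a warning (they convey no scale). ``sided`` is ``"two"``
    (coverage: gains and losses) or ``"upper"`` (burden/methylation: only
    increases are of interest).
    """
    if sided not in ("two", "upper"):
        raise ValueError(f"sided must be 'two' or 'upper', got {sided!r}")
    if not sample_values:
        raise ValueError("empty feature set")
    if len(reference) and isinstance(reference[0], ReferenceStats):
        ref_stats = {r.feature_id: r for r in reference}
        missing = [f for f in sample_values if f not in ref_stats]
        if missing:
            raise ValueError(f"features missing from reference: {missing[:5]}")
        stats_list = [ref_stats[f] for f in sample_values]
        if any(r.n < 2 for r in stats_list):
            raise ValueError("reference cohort must contain >= 2 samples")
    else:
        stats_list = compute_reference_stats(reference, features=sample_values.keys())

    kept = [r for r in stats_list if not r.excluded and r.s > 0]
    dropped = [r.feature_id for r in stats_list if r.excluded or r.s <= 0]
    if dropped:
        warnings.warn(
            f"excluding {len(dropped)} feature(s) with zero reference variance: "
            f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}"
        )
    if not kept:
        warnings.warn("all features have zero reference variance; empty result")
        return pd.DataFrame(columns=SCORE_COLUMNS)

    fid = [r.feature_id for r in kept]
    y = np.array([sample_values[f] for f in fid], dtype=float)
    m = np.array([r.m for r in kept])
    s = np.array([r.s for r in kept])
    n = kept[0].n
    z = (y - m) / s
    t = z / np.sqrt(1.0 + 1.0 / n)
    df = n - 1
    if sided == "two":
        p = 2.0 * stats.t.sf(np.abs(t), df)
        direction = np.where(z >= 0, "gain", "loss")
    else:
        p = stats.t.sf(t, df)
        direction = np.full(len(t), "increase", dtype=object)
    p = np.clip(p, _P_LO, 1.0)
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "feature_id": fid,
            "y": y,
            "z": z,
            "t": t,
            "p": p,
            "q": q,
            "significant": q < alpha,
            "direction": direction,
        }
    )


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _check_p(p, open_upper: bool) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    hi_bad = (p >= 1) if open_upper else (p > 1)
    if np.any((p <= 0) | hi_bad) or np.any(~np.isfinite(p)):
        raise ValueError("p-values out of range")
    return p


def stouffer(
    p: Sequence[float], weights: Sequence[float] | None = None
) -> tuple[float, float]:
    """Stouffer's weighted probit combination.

    z = sum(w_k * Phi^-1(1 - p_k)) / sqrt(sum(w_k^2)); combined
    p = 1 - Phi(z). Unweighted: all w_k = 1. Inputs are clipped to
    [1e-300, 1 - 1e-16] before the probit transform.
    """
    p = _check_p(p, open_upper=True)
    if weights is None:
        w = np.ones_like(p)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != p.shape:
            raise ValueError("weights must match p in length")
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be non-negative and not all zero")
    zk = ndtri(1.0 - np.clip(p, _P_LO, _P_HI))
    z = float(np.dot(w, zk) / np.sqrt(np.dot(w, w)))
    return z, float(ndtr(-z))


def fisher(p: Sequence[float]) -> tuple[float, float]:
    """Fisher's combination: S = -2 sum(log p), chi^2 with 2M df."""
    p = _check_p(p, open_upper=False)
    s = float(-2.0 * np.sum(np.log(np.clip(p, _P_LO, 1.0))))
    return s, float(stats.chi2.sf(s, 2 * p.size))


def combine_z(z: Sequence[float], weights: Sequence[float] | None = None) -> tuple[float, float]:
    """Stouffer combination of already-probit scores (z-scale inputs)."""
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValueError("empty z vector")
    if weights is None:
        w = np.ones_like(z)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != z.shape:
            raise ValueError("weights must match z in length")
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be non-negative and not all zero")
    zc = float(np.dot(w, z) / np.sqrt(np.dot(w, w)))
    return zc, float(ndtr(-zc))


def modality_score(
    scores: pd.DataFrame, alpha: float = 0.05, modality: str = "cna"
) -> ModalityScore:
    """Integrate a sample's per-feature scores into one modality score.

    Significant features (q < alpha) contribute their *uncorrected*
    p-values to a Stouffer combination. A sample with no significant
    features is neutral by convention: z = 0, p = 0.5 — matching the
    all-zero integrated scores observed in reference controls.
    """
    sig = scores[scores["q"] < alpha] if len(scores) else scores
    k = int(len(sig))
    if k == 0:
        return ModalityScore(modality, 0, 0.0, 0.5)
    z, p = stouffer(sig["p"].to_numpy())
    return ModalityScore(modality, k, z, p)
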