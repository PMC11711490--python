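"""In silico dilution of cancer templates for sensitivity evaluation.

Validation cohorts are simulated on the summary-feature level (arm coverage
aggregates, arm log10 mutation burdens, marker methylation logits), not on
reads. Control samples draw each feature from Normal(m_k, s_k^2), with
(m_k, s_k) estimated from non-cancer reference samples. Cancer samples at a
target ctDNA fraction r are admixtures of a tumour template (a real or
synthetic cancer plasma profile with known fraction rho):

    y_k = w * x_k^t + (1 - w) * x_k^h,   w = r / rho,

where x_k^h is a fresh control draw. Sweeping r and scoring every simulated
sample with the reference-cohort/multimodal machinery yields an AUC-versus-
fraction curve — the pipeline's in silico limit of detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats
from scipy.special import ndtr, ndtri

from .multimodal import rank_auc

__all__ = [
    "ModalityTemplate",
    "TemplateStats",
    "SimCohort",
    "make_synthetic_templates",
    "simulate_sample",
    "simulate_cohort",
    "score_cohort",
    "evaluate_auc",
]


@dataclass(frozen=True)
class ModalityTemplate:
    """Per-feature control statistics and tumour-template values for one
    modality. ``sided`` is the test direction used when scoring."""

    features: tuple[str, ...]
    m: np.ndarray  # control mean per feature
    s: np.ndarray  # control SD per feature
    x_t: np.ndarray  # tumour-template value per feature
    sided: str = "two"


@dataclass(frozen=True)
class TemplateStats:
    """Templates for all modalities plus the tumour template's fraction."""

    modalities: dict[str, ModalityTemplate]
    template_rho: float
    n_ref: int = 9  # reference-cohort size backing (m, s)

    def __post_init__(self):
        if not (0.0 < self.template_rho <= 1.0):
            raise ValueError("template_rho must lie in (0, 1]")


@dataclass
class SimCohort:
    fractions: np.ndarray  # per-sample target fraction
    labels: np.ndarray  # 1 = case, 0 = control
    features: dict[str, np.ndarray]  # modality -> (n_samples, n_features)
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.labels)


def make_synthetic_templates(
    seed: int = 0,
    n_arms: int = 39,
    n_markers: int = 377,
    template_rho: float = 0.09,
    n_ref: int = 9,
) -> TemplateStats:
    """Synthetic study templates emulating a colorectal-like tumour profile.

    Control statistics mimic a denoised reference cohort: arm coverage
    aggregates centred near zero with per-arm SDs of a few thousandths of a
    log2 unit, per-arm log10 mutation burdens around 0.7 (a handful of
    passenger calls per arm), and near-zero marker methylation on the
    empirical-logit scale. The tumour template carries arm gains/losses of
    the size produced by single-copy events at the template's 9% tumour
    fraction, elevated burden on a subset of arms, and strong
    hypermethylation on a subset of markers.
    """
    rng = np.random.default_rng(seed)
    arm_ids = tuple(f"arm_{i}" for i in range(n_arms))
    marker_ids = tuple(f"marker_{i}" for i in range(n_markers))

    # coverage: aggregate log2 signal; one-copy gain at rho=9% shifts an arm
    # by log2(1 + rho/2) ~ 0.063
    cov_m = rng.normal(0.0, 0.005, n_arms)
    cov_s = rng.uniform(0.004, 0.008, n_arms)
    cov_t = cov_m.copy()
    aberrant = rng.choice(n_arms, size=12, replace=False)
    signs = rng.choice([-1.0, 1.0], size=12)
    cov_t[aberrant] += signs * np.log2(1.0 + template_rho / 2.0)

    # burden: log10(count+1) per arm; controls ~5 calls/arm
    bur_m = rng.normal(0.72, 0.03, n_arms)
    bur_s = rng.uniform(0.05, 0.09, n_arms)
    bur_t = bur_m.copy()
    hot = rng.choice(n_arms, size=15, replace=False)
    bur_t[hot] += rng.uniform(0.25, 0.45, 15)

    # methylation: empirical logit of tumour-fragment fraction; controls
    # are curated to near-zero fractions
    met_m = rng.normal(-4.1, 0.05, n_markers)
    met_s = rng.uniform(0.15, 0.3, n_markers)
    met_t = met_m.copy()
    planted = rng.choice(n_markers, size=150, replace=False)
    met_t[planted] = rng.normal(-1.4, 0.3, 150)

    return TemplateStats(
        modalities={
            "cna": ModalityTemplate(arm_ids, cov_m, cov_s, cov_t, sided="two"),
            "snv": ModalityTemplate(arm_ids, bur_m, bur_s, bur_t, sided="upper"),
            "meth": ModalityTemplate(marker_ids, met_m, met_s, met_t, sided="upper"),
        },
        template_rho=template_rho,
        n_ref=n_ref,
    )


def simulate_sample(
    templates: TemplateStats,
    r: float,
    label: str,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """One simulated sample's feature vectors per modality.

    Controls draw Normal(m_k, s_k); cases mix the tumour template with a
    fresh control draw at weight w = r / template_rho (so r equal to the
    template's fraction reproduces the template exactly, and r -> 0
    degenerates to the control distribution). ``s_k`` is a standard
    deviation throughout.
    """
    if label not in ("case", "control"):
        raise ValueError("label must be 'case' or 'control'")
    out = {}
    for name, t in templates.modalities.items():
        x_h = t.m + t.s * rng.standard_normal(len(t.m))
        if label == "control":
            out[name] = x_h
        else:
            w = r / templates.template_rho
            if w > 1.0 + 1e-12:
                raise ValueError(
                    f"target fraction {r} exceeds template fraction "
                    f"{templates.template_rho}"
                )
            out[name] = w * t.x_t + (1.0 - w) * x_h
    return out


def simulate_cohort(
    templates: TemplateStats,
    fractions,
    n_per_group: int,
    seed: int | None = 0,
) -> SimCohort:
    """Case/control cohort across target fractions (vectorised).

    Every fraction contributes ``n_per_group`` cases and ``n_per_group``
    controls, so len(cohort) = len(fractions) * 2 * n_per_group. The cohort
    is bitwise reproducible for a fixed seed.
    """
    fractions = np.asarray(list(fractions), dtype=float)
    rng = np.random.default_rng(seed)
    n_total = len(fractions) * 2 * n_per_group
    frac_col = np.repeat(fractions, 2 * n_per_group)
    labels = np.tile(
        np.concatenate([np.ones(n_per_group, int), np.zeros(n_per_group, int)]),
        len(fractions),
    )
    feats: dict[str, np.ndarray] = {}
    for name, t in templates.modalities.items():
        k = len(t.m)
        x_h = t.m + t.s * rng.standard_normal((n_total, k))
        w = np.where(labels == 1, frac_col / templates.template_rho, 0.0)
        if np.any(w > 1.0 + 1e-12):
            raise ValueError("a target fraction exceeds the template fraction")
        feats[name] = w[:, None] * t.x_t + (1.0 - w[:, None]) * x_h
    return SimCohort(fractions=frac_col, labels=labels, features=feats, seed=seed)


def _bh_rows(p: np.ndarray) -> np.ndarray:
    """Row-wise Benjamini-Hochberg over a (n_samples, k) p-value matrix."""
    n, k = p.shape
    order = np.argsort(p, axis=1)
    sorted_p = np.take_along_axis(p, order, axis=1)
    q = sorted_p * k / np.arange(1, k + 1)
    q = np.minimum.accumulate(q[:, ::-1], axis=1)[:, ::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty_like(q)
    np.put_along_axis(out, order, q, axis=1)
    return out


def score_cohort(
    cohort: SimCohort,
    templates: TemplateStats,
    alpha: float = 0.05,
) -> dict[str, np.ndarray]:
    """Score every simulated sample with the reference-cohort machinery.

    Vectorised equivalent of per-sample ``score_features`` +
    ``modality_score`` + Stouffer integration against the template's
    (m_k, s_k, N): per-modality z and the equal-weight combined z per
    sample. Returns {"cna": z, "snv": z, "meth": z, "combined": z,
    "p": combined p}.
    """
    n_ref = templates.n_ref
    zs = {}
    for name, t in templates.modalities.items():
        y = cohort.features[name]
        z = (y - t.m) / t.s
        tt = z / np.sqrt(1.0 + 1.0 / n_ref)
        if t.sided == "two":
            p = 2.0 * sstats.t.sf(np.abs(tt), n_ref - 1)
        else:
            p = sstats.t.sf(tt, n_ref - 1)
        p = np.clip(p, 1e-300, 1.0)
        q = _bh_rows(p)
        sig = q < alpha
        zfeat = ndtri(1.0 - np.clip(p, 1e-300, 1.0 - 1e-16))
        ksig = sig.sum(axis=1)
        num = np.where(sig, zfeat, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            zm = np.where(ksig > 0, num / np.sqrt(np.maximum(ksig, 1)), 0.0)
        zs[name] = zm
    names = list(templates.modalities)
    combined = np.sum([zs[n] for n in names], axis=0) / np.sqrt(len(names))
    zs["combined"] = combined
    zs["p"] = ndtr(-combined)
    return zs


def evaluate_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC (tie half-credit) of case-versus-control scores."""
    return rank_auc(scores, labels)


def auc_by_fraction(
    cohort: SimCohort, scores: np.ndarray
) -> dict[float, float]:
    """AUC computed separately within each simulated target fraction."""
    out = {}
    for r in np.unique(cohort.fractions):
        sel = cohort.fractions == r
        out[float(r)] = evaluate_auc(scores[sel], cohort.labels[sel])
    return out
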