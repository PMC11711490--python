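"""Multimodal integration, screening arithmetic and cross-validated evaluation.

The three per-modality scores (copy number, mutation burden, fragment
methylation) each yield a probit score z_m with p_m = 1 - Phi(z_m). They are
integrated with Stouffer's weighted method,

    z = sum(w_m z_m) / sqrt(sum(w_m^2)),   p = 1 - Phi(z),

calling a sample ctDNA-positive at p < 0.05; Fisher's method
(S = -2 sum log p_m, chi^2 with 2M df) is the drop-in alternative. Missing
modalities are simply absent from the sum. Screening arithmetic converts a
(sensitivity, specificity, prevalence) triple into predictive values, and a
leave-one-out harness evaluates integration rules or pluggable classifier
cores on a cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.special import ndtr, ndtri

from .refstats import ModalityScore, combine_z, fisher as fisher_combine

__all__ = [
    "MultimodalResult",
    "ScreeningPerformance",
    "CVReport",
    "combine_modalities",
    "screening_performance",
    "score_change",
    "origin_features",
    "loo_cv",
    "rank_auc",
]

CALL_ALPHA = 0.05


@dataclass(frozen=True)
class MultimodalResult:
    sample_id: str
    modalities: tuple[ModalityScore, ...]
    weights: tuple[float, ...]
    z: float
    p: float
    call: bool
    method: str = "stouffer"


@dataclass(frozen=True)
class ScreeningPerformance:
    sensitivity: float
    specificity: float
    prevalence: float
    npv: float
    ppv: float
    post_test_negative: float


@dataclass
class CVReport:
    predictions: pd.DataFrame  # per held-out subject
    auc: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    balanced_accuracy: float | None = None
    confusion: pd.DataFrame | None = None
    case_weights: dict = field(default_factory=dict)


def combine_modalities(
    scores: Sequence[ModalityScore],
    weights: Sequence[float] | None = None,
    method: str = "stouffer",
    sample_id: str = "sample",
    alpha: float = CALL_ALPHA,
) -> MultimodalResult:
    """Integrate 1-3 modality scores into a sample-level cancer call.

    Stouffer operates on the modality z scores directly; Fisher on the
    modality p-values. Zero-weight modalities drop out; absent modalities
    are simply not passed in.
    """
    if not scores:
        raise ValueError("at least one modality score is required")
    if weights is None:
        w = np.ones(len(scores))
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(scores):
            raise ValueError("weights must match the number of modalities")
    if method == "stouffer":
        z, p = combine_z([s.z for s in scores], w)
    elif method == "fisher":
        keep = w > 0
        pv = np.array([s.p for s in scores])[keep]
        if pv.size == 0:
            raise ValueError("all modality weights are zero")
        _, p = fisher_combine(pv)
        z = float(ndtri(1.0 - min(max(p, 1e-300), 1 - 1e-16)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return MultimodalResult(
        sample_id=sample_id,
        modalities=tuple(scores),
        weights=tuple(float(x) for x in w),
        z=z,
        p=p,
        call=bool(p < alpha),
        method=method,
    )


def screening_performance(
    sensitivity: float, specificity: float, prevalence: float
) -> ScreeningPerformance:
    """Predictive values of a screening test at a given prevalence.

    npv = spec(1-prev) / (spec(1-prev) + (1-sens)prev);
    ppv = sens*prev / (sens*prev + (1-spec)(1-prev));
    post-test probability of cancer after a negative result = 1 - npv.
    """
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity),
                    ("prevalence", prevalence)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    neg_den = specificity * (1 - prevalence) + (1 - sensitivity) * prevalence
    pos_den = sensitivity * prevalence + (1 - specificity) * (1 - prevalence)
    if neg_den == 0 or pos_den == 0:
        raise ValueError("degenerate test: no positive or no negative results")
    npv = specificity * (1 - prevalence) / neg_den
    ppv = sensitivity * prevalence / pos_den
    return ScreeningPerformance(
        sensitivity, specificity, prevalence, npv, ppv, 1.0 - npv
    )


def score_change(pre_score: float, post_score: float) -> float:
    """Percent reduction of a ctDNA score between two timepoints."""
    if pre_score <= 0:
        raise ValueError("pre-treatment score must be positive")
    return 100.0 * (pre_score - post_score) / pre_score


def origin_features(
    arm_coverage: Mapping[str, float],
    arm_burdens: Mapping[str, float],
    marker_elogits: Mapping[str, float],
    arm_universe: Sequence[str],
    marker_universe: Sequence[str],
) -> tuple[np.ndarray, list[str]]:
    """Fixed-order feature vector for cancer-origin classification.

    Concatenates (arm coverage || arm burden || marker elogits) in the order
    given by the universes; the feature-name index is returned alongside.
    """
    missing = (
        [a for a in arm_universe if a not in arm_coverage]
        + [a for a in arm_universe if a not in arm_burdens]
        + [m for m in marker_universe if m not in marker_elogits]
    )
    if missing:
        raise ValueError(f"feature universes mismatch; missing: {missing[:5]}")
    names = (
        [f"cov:{a}" for a in arm_universe]
        + [f"snv:{a}" for a in arm_universe]
        + [f"meth:{m}" for m in marker_universe]
    )
    vec = np.array(
        [arm_coverage[a] for a in arm_universe]
        + [arm_burdens[a] for a in arm_universe]
        + [marker_elogits[m] for m in marker_universe],
        dtype=float,
    )
    return vec, names


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-statistic AUC with half credit for ties (Mann-Whitney)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1, n0 = labels.sum(), (~labels).sum()
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = sstats.rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _case_weights(y_train: np.ndarray) -> np.ndarray:
    """max(group sizes) / own group size, per training case."""
    vals, counts = np.unique(y_train, return_counts=True)
    size = dict(zip(vals, counts))
    m = counts.max()
    return np.array([m / size[y] for y in y_train], dtype=float)


def _make_classifier(model: str, seed: int | None):
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.svm import SVC

    if model == "logistic":
        return LogisticRegression(max_iter=1000)
    if model == "rf":
        return RandomForestClassifier(random_state=seed)
    if model == "svm":
        return SVC(probability=True, random_state=seed)
    raise ValueError(f"unknown model {model!r}")


def _fit_multinomial_inner_loo(X, y, w, Cs, seed):
    """Penalised multinomial core: the L1 penalty is the one hyperparameter
    tuned, by an inner leave-one-out loop on the training data only."""
    from sklearn.linear_model import LogisticRegression

    best_C, best_acc = Cs[0], -1.0
    for C in Cs:
        hits = 0
        for i in range(len(y)):
            tr = np.ones(len(y), dtype=bool)
            tr[i] = False
            if len(np.unique(y[tr])) < 2:
                continue
            clf = LogisticRegression(
                penalty="l1", solver="saga", C=C, max_iter=500, random_state=seed
            )
            clf.fit(X[tr], y[tr], sample_weight=w[tr])
            hits += int(clf.predict(X[i : i + 1])[0] == y[i])
        acc = hits / len(y)
        if acc > best_acc:
            best_acc, best_C = acc, C
    clf = LogisticRegression(
        penalty="l1", solver="saga", C=best_C, max_iter=1000, random_state=seed
    )
    clf.fit(X, y, sample_weight=w)
    return clf


def loo_cv(
    X: np.ndarray,
    labels: Sequence,
    model: str = "stouffer",
    alpha: float = CALL_ALPHA,
    positive_label=1,
    seed: int | None = 0,
    multinomial_Cs: Sequence[float] = (0.01, 0.1, 1.0, 10.0),
) -> CVReport:
    """Leave-one-out evaluation of an integration rule or classifier.

    For ``model`` in {"stouffer", "fisher"} the rows of ``X`` are modality
    z scores (stouffer) or p-values (fisher); nothing is trained and each
    subject's combined p is thresholded at ``alpha``. For classifier cores
    ({"logistic", "rf", "svm", "multinomial"}) each subject is predicted by
    a model trained on all others with case weights max(n_g)/n_g. Classes
    with a single member are excluded from multi-class runs (they cannot be
    predicted by a model that never saw them).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    if X.ndim == 1:
        X = X[:, None]
    vals, counts = np.unique(y, return_counts=True)
    if len(vals) < 2:
        raise ValueError("need at least two classes")
    multiclass = len(vals) > 2
    if multiclass and (counts == 1).any():
        drop = set(vals[counts == 1])
        warnings.warn(f"excluding single-member class(es): {sorted(map(str, drop))}")
        keep = ~np.isin(y, list(drop))
        X, y = X[keep], y[keep]
        vals, counts = np.unique(y, return_counts=True)
        # stay in multi-class reporting mode: the task was multi-class even
        # if exclusions leave only two predictable classes

    n = len(y)
    rows = []
    if model in ("stouffer", "fisher"):
        for i in range(n):
            if model == "stouffer":
                z, p = combine_z(X[i])
            else:
                _, p = fisher_combine(np.clip(X[i], 1e-300, 1.0))
                z = float(ndtri(1 - min(p, 1 - 1e-16)))
            rows.append({"index": i, "label": y[i], "score": z, "p": p,
                         "predicted": positive_label if p < alpha else _other(vals, positive_label)})
        weights_used: dict = {}
    else:
        weights_used = {}
        for i in range(n):
            tr = np.ones(n, dtype=bool)
            tr[i] = False
            w = _case_weights(y[tr])
            weights_used = {str(v): float(counts.max() / c) for v, c in zip(vals, counts)}
            if model == "multinomial":
                clf = _fit_multinomial_inner_loo(X[tr], y[tr], w, multinomial_Cs, seed)
            else:
                clf = _make_classifier(model, seed)
                clf.fit(X[tr], y[tr], sample_weight=w)
            pred = clf.predict(X[i : i + 1])[0]
            if not multiclass and hasattr(clf, "predict_proba"):
                pos_idx = list(clf.classes_).index(positive_label)
                score = float(clf.predict_proba(X[i : i + 1])[0, pos_idx])
            else:
                score = np.nan
            rows.append({"index": i, "label": y[i], "score": score, "p": np.nan,
                         "predicted": pred})
    preds = pd.DataFrame(rows)

    report = CVReport(predictions=preds, case_weights=weights_used)
    if not multiclass:
        is_pos = preds["label"].to_numpy() == positive_label
        pred_pos = preds["predicted"].to_numpy() == positive_label
        score = preds["score"].to_numpy(dtype=float)
        report.auc = rank_auc(score, is_pos)
        report.sensitivity = float(pred_pos[is_pos].mean()) if is_pos.any() else None
        report.specificity = float((~pred_pos[~is_pos]).mean()) if (~is_pos).any() else None
    else:
        cm = pd.crosstab(preds["label"], preds["predicted"], dropna=False)
        cm = cm.reindex(index=vals, columns=vals, fill_value=0)
        recalls = [cm.loc[v, v] / cm.loc[v].sum() if cm.loc[v].sum() else 0.0 for v in vals]
        report.balanced_accuracy = float(np.mean(recalls))
        report.confusion = cm
    return report


def _other(vals, positive_label):
    others = [v for v in vals if v != positive_label]
    return others[0] if others else positive_label
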