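"""Biomarker panel evaluation.

Multivariate logistic models on log10(NMP+1) marker levels, assessed by
leave-one-out cross-validation: one out-of-fold probability per sample,
a single pooled ROC curve, AUC with DeLong 95% CI, the Youden-index
operating point with exact (Clopper-Pearson) sensitivity/specificity
intervals, and detection-rate tables by lesion subtype and location.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContrastSpec",
    "LogisticFit",
    "RocResult",
    "fit_logistic",
    "predict_proba",
    "loocv_probabilities",
    "roc_curve",
    "roc_auc",
    "youden_cutoff",
    "detection_rates",
    "evaluate_contrast",
]


@dataclass
class ContrastSpec:
    """A classification task: positive vs negative pathology groups."""

    name: str
    positive: frozenset[str]
    negative: frozenset[str]
    markers: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.positive & self.negative:
            raise ValueError("positive and negative groups overlap")
        if not self.markers:
            raise ValueError("need >= 1 marker")


@dataclass
class LogisticFit:
    coef: np.ndarray  # [intercept, per-feature...]
    converged: bool
    separated: bool
    deviance: float
    n_iter: int


def _design(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X])


def fit_logistic(X, y, max_iter: int = 100, tol: float = 1e-8) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS (no penalty).

    Convergence on |change in deviance| < ``tol``. Complete separation is
    detected (deviance collapsing to zero with runaway coefficients) and
    flagged rather than suppressed: the coefficients are unstable but the
    fitted probabilities remain usable.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    A = _design(X)
    beta = np.zeros(A.shape[1])
    dev_old = np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = np.clip(A @ beta, -30, 30)
        p = 1 / (1 + np.exp(-eta))
        w = np.maximum(p * (1 - p), 1e-10)
        z = eta + (y - p) / w
        Aw = A * w[:, None]
        beta = np.linalg.solve(A.T @ Aw + 1e-12 * np.eye(A.shape[1]), A.T @ (w * z))
        eta = np.clip(A @ beta, -30, 30)
        p = np.clip(1 / (1 + np.exp(-eta)), 1e-15, 1 - 1e-15)
        dev = -2 * float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
        if abs(dev_old - dev) < tol:
            converged = True
            dev_old = dev
            break
        dev_old = dev
    separated = dev_old < 1e-6
    return LogisticFit(coef=beta, converged=converged, separated=separated,
                       deviance=float(dev_old), n_iter=n_iter)


def predict_proba(fit: LogisticFit, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    eta = np.clip(_design(X) @ fit.coef, -30, 30)
    return 1 / (1 + np.exp(-eta))


def loocv_probabilities(X, y) -> np.ndarray:
    """Out-of-fold probability per sample: fit on all others, predict it.

    Deterministic given the data. Folds whose training labels collapse to
    one class return that class's empirical rate.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need >= 3 samples for leave-one-out")
    probs = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            probs[i] = float(y[mask].mean())
            continue
        fit = fit_logistic(X[mask], y[mask])
        probs[i] = float(predict_proba(fit, X[i:i + 1])[0])
    return probs


def roc_curve(probabilities, labels) -> pd.DataFrame:
    """All achievable (FPR, TPR) operating points (prob >= threshold is a
    positive call), from the all-negative to the all-positive corner."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    thresholds = np.concatenate([[np.inf], np.unique(p)[::-1]])
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    rows = []
    for thr in thresholds:
        pred = p >= thr
        rows.append({"threshold": thr,
                     "tpr": float((pred & (y == 1)).sum() / n_pos) if n_pos else 0.0,
                     "fpr": float((pred & (y == 0)).sum() / n_neg) if n_neg else 0.0})
    return pd.DataFrame(rows)


def _auc_rank(p: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC with half credit for ties."""
    ranks = stats.rankdata(p)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _delong_ci(p: np.ndarray, y: np.ndarray, auc: float, level: float = 0.95):
    x, w = p[y == 1], p[y == 0]
    m, n = len(x), len(w)
    psi = (x[:, None] > w[None, :]).astype(float) + 0.5 * (x[:, None] == w[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    var = (v10.var(ddof=1) / m if m > 1 else 0.0) + (v01.var(ddof=1) / n if n > 1 else 0.0)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(max(var, 0.0))
    return max(0.0, auc - half), min(1.0, auc + half)


def _exact_ci(k: int, n: int, level: float = 0.95):
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=level, method="exact")
    return float(ci.low), float(ci.high)


@dataclass
class RocResult:
    """LOOCV classification performance bundle."""

    auc: float
    auc_ci: tuple[float, float]
    cutoff: float
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    curve: pd.DataFrame
    probabilities: pd.Series
    detection: pd.DataFrame | None = None
    location_test_p: float | None = None
    separated: bool = False
    extras: dict = field(default_factory=dict)


def roc_auc(probabilities, labels) -> tuple[float, tuple[float, float], pd.DataFrame]:
    """AUC (rank formulation, ties get half credit), DeLong 95% CI, and
    the ROC curve."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    auc = _auc_rank(p, y)
    return auc, _delong_ci(p, y, auc), roc_curve(p, y)


def youden_cutoff(probabilities, labels) -> tuple[float, float, float]:
    """Operating point maximizing J = sensitivity + specificity − 1 over
    the observed thresholds; ties resolve toward higher specificity
    (higher threshold). Returns (cutoff, sensitivity, specificity)."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    best = None
    for thr in np.unique(p):  # prob >= thr called positive
        pred = p >= thr
        sens = float((pred & (y == 1)).sum() / max(y.sum(), 1))
        spec = float((~pred & (y == 0)).sum() / max((1 - y).sum(), 1))
        j = sens + spec - 1
        key = (j, spec, thr)
        if best is None or key > best[0]:
            best = (key, thr, sens, spec)
    return best[1], best[2], best[3]


def detection_rates(
    probabilities: pd.Series,
    labels: pd.Series,
    cutoff: float,
    subtype: pd.Series,
    location: pd.Series | None = None,
) -> tuple[pd.DataFrame, float | None]:
    """Per-subtype detection rates among positive samples, plus a Fisher
    exact test of detected/undetected against distal/proximal location.

    A subtype with no positive samples is reported as NaN, never 0.
    """
    pos = labels[labels == 1].index
    missing = pos.difference(subtype.index)
    if len(missing):
        raise KeyError(f"metadata missing for positive samples: {list(missing[:5])}")
    detected = probabilities >= cutoff
    rows = []
    for st in pd.unique(subtype.loc[pos]):
        members = [s for s in pos if subtype[s] == st]
        rate = 100.0 * detected[members].mean() if members else float("nan")
        rows.append({"subtype": st, "n": len(members),
                     "n_detected": int(detected[members].sum()),
                     "detection_rate_pct": rate})
    table = pd.DataFrame(rows)

    loc_p = None
    if location is not None:
        loc = location.reindex(pos)
        use = loc.isin(["distal", "proximal"])
        if use.any():
            det = detected[pos[use]]
            dist = loc[use] == "distal"
            tab = [[int((det & dist).sum()), int((det & ~dist).sum())],
                   [int((~det & dist).sum()), int((~det & ~dist).sum())]]
            loc_p = float(stats.fisher_exact(tab, alternative="two-sided")[1])
    return table, loc_p


def evaluate_contrast(
    features: pd.DataFrame,
    sheet: pd.DataFrame,
    spec: ContrastSpec,
    subtype_col: str | None = None,
    location_col: str | None = None,
) -> RocResult:
    """LOOCV evaluation of one marker panel on one contrast.

    ``features`` holds log10(NMP+1) values (samples x markers); samples
    are labelled positive/negative from the sample sheet's group column
    and samples outside the contrast are ignored.
    """
    groups = sheet.loc[features.index, "group"]
    keep = groups.isin(spec.positive | spec.negative)
    sub = features.loc[keep, list(spec.markers)]
    y = groups[keep].isin(spec.positive).astype(int)
    probs = loocv_probabilities(sub.to_numpy(), y.to_numpy())
    probs = pd.Series(probs, index=sub.index, name="probability")
    auc, auc_ci, curve = roc_auc(probs.to_numpy(), y.to_numpy())
    cutoff, sens, spec_ = youden_cutoff(probs.to_numpy(), y.to_numpy())
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    sens_ci = _exact_ci(round(sens * n_pos), n_pos)
    spec_ci = _exact_ci(round(spec_ * n_neg), n_neg)
    full_fit = fit_logistic(sub.to_numpy(), y.to_numpy())

    detection, loc_p = None, None
    if subtype_col is not None and subtype_col in sheet.columns:
        detection, loc_p = detection_rates(
            probs, y, cutoff, sheet.loc[sub.index, subtype_col],
            sheet.loc[sub.index, location_col] if location_col in sheet.columns else None,
        )
    return RocResult(
        auc=auc, auc_ci=auc_ci, cutoff=cutoff,
        sensitivity=sens, sensitivity_ci=sens_ci,
        specificity=spec_, specificity_ci=spec_ci,
        curve=curve, probabilities=probs,
        detection=detection, location_test_p=loc_p,
        separated=full_fit.separated,
        extras={"n_positive": n_pos, "n_negative": n_neg, "name": spec.name},
    )
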