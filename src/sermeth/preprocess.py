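"""Probe filtering, batch adjustment and beta/M conversion.

The array analysis works on two scales: beta values (methylated signal
fraction, in [0,1], reported for interpretability) and M values (logit2
of beta, approximately Gaussian, used for all statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "beta_to_m",
    "m_to_beta",
    "FilterPolicy",
    "FilterReport",
    "filter_probes",
    "assumption_filter",
    "combat_adjust",
    "select_most_variable",
]


def beta_to_m(beta: pd.DataFrame, clip_eps: float = 1e-6) -> pd.DataFrame:
    """logit2 transform: M = log2(b / (1 - b)) with b clipped to
    [clip_eps, 1 - clip_eps] so the result is finite everywhere."""
    if not 0 < clip_eps < 0.5:
        raise ValueError("clip_eps must lie in (0, 0.5)")
    b = beta.clip(lower=clip_eps, upper=1 - clip_eps)
    return np.log2(b / (1 - b))


def m_to_beta(m: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`beta_to_m`: beta = 2^M / (2^M + 1)."""
    p = np.exp2(m)
    return p / (p + 1)


@dataclass
class FilterPolicy:
    """Probe-exclusion policy, applied in a fixed order."""

    detection_p_max: float = 0.01
    min_bead_count: int = 3
    drop_cross_reactive: bool = True
    drop_snp: bool = True
    drop_sex_chrom: bool = True


@dataclass
class FilterReport:
    """Removal counts per criterion, in application order, plus QC."""

    n_input: int
    n_output: int
    removed: dict[str, int] = field(default_factory=dict)
    mean_detection_p_per_sample: dict[str, float] = field(default_factory=dict)


def filter_probes(
    beta: pd.DataFrame,
    det,
    ann: pd.DataFrame,
    policy: FilterPolicy | None = None,
    assumption_keep: pd.Series | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Discard low-quality and masked probes.

    Criteria, applied in order with each removal attributed to the first
    criterion that catches it: detection p > threshold in any sample;
    bead count < minimum in any sample; cross-reactive mask; SNP mask;
    sex chromosomes; optional regression-assumption mask. Also reports
    the mean detection p per sample for failed-sample QC.
    """
    policy = policy or FilterPolicy()
    missing = beta.index.difference(ann.index)
    if len(missing):
        raise KeyError(f"annotation missing probes: {list(missing[:10])}")
    ann = ann.loc[beta.index]
    det_p = det.detection_p.loc[beta.index, beta.columns]
    beads = det.bead_count.loc[beta.index, beta.columns]

    report = FilterReport(n_input=len(beta), n_output=0)
    report.mean_detection_p_per_sample = det_p.mean(axis=0).to_dict()

    alive = pd.Series(True, index=beta.index)

    def drop(name: str, bad: pd.Series) -> None:
        hit = bad & alive
        report.removed[name] = int(hit.sum())
        alive[hit] = False

    drop("detection_p", (det_p > policy.detection_p_max).any(axis=1))
    drop("bead_count", (beads < policy.min_bead_count).any(axis=1))
    drop("cross_reactive",
         ann["cross_reactive"] if policy.drop_cross_reactive else pd.Series(False, index=beta.index))
    drop("snp", ann["snp"] if policy.drop_snp else pd.Series(False, index=beta.index))
    drop("sex_chrom",
         ann["sex_chrom"] if policy.drop_sex_chrom else pd.Series(False, index=beta.index))
    if assumption_keep is not None:
        drop("assumptions", ~assumption_keep.reindex(beta.index, fill_value=True))
    else:
        report.removed["assumptions"] = 0

    out = beta.loc[alive]
    report.n_output = len(out)
    return out, report


def assumption_filter(
    m: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Screen probes for violations of the linear-model assumptions.

    Per probe, M is regressed on the group factor and the standardized
    residuals are put through four diagnostics: Shapiro-Wilk normality,
    Breusch-Pagan homoscedasticity against the fitted values,
    Durbin-Watson serial correlation in sample order (flag outside
    [1, 3]), and a RESET-style linearity check (significance of the
    squared fitted value in an auxiliary regression; skipped when the
    fitted values take fewer than three distinct levels). A probe is
    dropped if any diagnostic rejects at ``alpha``; zero-residual
    (degenerate) probes are dropped with an explicit reason.

    Returns a frame indexed by probe with a boolean ``keep`` column, the
    individual test statistics and a ``reason`` string.
    """
    from statsmodels.stats.diagnostic import het_breuschpagan
    from statsmodels.stats.stattools import durbin_watson

    groups = groups.loc[m.columns]
    counts = groups.value_counts()
    if (counts < 3).any():
        raise ValueError("need >= 3 samples per group for the assumption screen")
    levels = list(counts.index)
    g_idx = groups.map({g: i for i, g in enumerate(levels)}).to_numpy()
    n, k = m.shape[1], len(levels)
    if n <= k:
        raise ValueError("fewer samples than model parameters")

    Y = m.to_numpy()
    # one-way fit: fitted value = group mean; leverage = 1/n_g
    sums = np.zeros((Y.shape[0], k))
    for i in range(k):
        sums[:, i] = Y[:, g_idx == i].sum(axis=1)
    means = sums / counts[levels].to_numpy()
    fitted = means[:, g_idx]
    resid = Y - fitted
    dof = n - k
    s2 = (resid**2).sum(axis=1) / dof
    lev = (1.0 / counts[levels].to_numpy())[g_idx]

    rows = []
    aux = np.column_stack([np.ones(n), g_idx])  # BP exog: const + fitted added per probe
    for i in range(Y.shape[0]):
        if s2[i] <= 1e-12:
            rows.append({"keep": False, "shapiro_p": np.nan, "bp_p": np.nan,
                         "dw": np.nan, "linearity_p": np.nan, "reason": "degenerate"})
            continue
        std_res = resid[i] / np.sqrt(s2[i] * (1 - lev))
        reasons = []
        sw_p = float(stats.shapiro(std_res).pvalue)
        if sw_p < alpha:
            reasons.append("normality")
        exog = np.column_stack([np.ones(n), fitted[i]])
        if np.ptp(fitted[i]) > 1e-12:
            bp_p = float(het_breuschpagan(resid[i], exog)[1])
        else:
            bp_p = np.nan
        if bp_p == bp_p and bp_p < alpha:
            reasons.append("homoscedasticity")
        dw = float(durbin_watson(resid[i]))
        if not (1.0 <= dw <= 3.0):
            reasons.append("uncorrelatedness")
        lin_p = np.nan
        if len(np.unique(np.round(fitted[i], 12))) >= 3:
            X = np.column_stack([np.ones(n), fitted[i], fitted[i] ** 2])
            coef, res_ss, rank, _ = np.linalg.lstsq(X, Y[i], rcond=None)
            if rank == 3 and n > 3:
                rss = float(res_ss[0]) if len(res_ss) else float(((Y[i] - X @ coef) ** 2).sum())
                sigma2 = rss / (n - 3)
                if sigma2 > 1e-12:
                    cov = np.linalg.inv(X.T @ X) * sigma2
                    tstat = coef[2] / np.sqrt(cov[2, 2])
                    lin_p = float(2 * stats.t.sf(abs(tstat), n - 3))
                    if lin_p < alpha:
                        reasons.append("linearity")
        rows.append({"keep": not reasons, "shapiro_p": sw_p, "bp_p": bp_p,
                     "dw": dw, "linearity_p": lin_p, "reason": ";".join(reasons)})
    _ = aux
    return pd.DataFrame(rows, index=m.index)


def combat_adjust(
    m: pd.DataFrame,
    batch: pd.Series,
    protect: pd.Series | None = None,
) -> pd.DataFrame:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Per probe, the data are standardized while preserving the protected
    covariate (biological group) effects, per-batch means get a Normal
    prior and per-batch variances an Inverse-Gamma prior with
    method-of-moments hyperparameters, the shrunken batch parameters are
    removed, and the data are back-transformed. With a single batch the
    input is returned unchanged.
    """
    batch = batch.loc[m.columns].astype(str)
    batches = list(pd.unique(batch))
    if len(batches) == 1:
        return m.copy()
    sizes = batch.value_counts()
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ValueError(f"batch variance undefined for single-sample batches: {small}")

    n = m.shape[1]
    B = pd.get_dummies(batch, dtype=float)[batches].to_numpy()  # n x n_batch
    if protect is not None:
        protect = protect.loc[m.columns].astype(str)
        G = pd.get_dummies(protect, dtype=float).to_numpy()[:, 1:]  # drop first level
    else:
        G = np.empty((n, 0))
    X = np.hstack([B, G])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("batch is confounded with the protected covariate")

    Y = m.to_numpy()  # probes x samples
    beta_hat = np.linalg.solve(X.T @ X, X.T @ Y.T)  # (n_batch+q) x probes
    nb = len(batches)
    w = sizes[batches].to_numpy() / n
    grand = w @ beta_hat[:nb]  # probe-wise weighted grand mean
    stand_mean = grand[:, None] + (G @ beta_hat[nb:]).T
    var_pooled = ((Y - (X @ beta_hat).T) ** 2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-12)
    s = (Y - stand_mean) / np.sqrt(var_pooled)[:, None]

    adjusted = s.copy()
    for bi, b in enumerate(batches):
        cols = (batch == b).to_numpy()
        nb_i = int(cols.sum())
        g_hat = s[:, cols].mean(axis=1)
        d_hat = s[:, cols].var(axis=1, ddof=1)
        g_bar, t2 = float(g_hat.mean()), float(g_hat.var(ddof=1))
        d_m, d_s2 = float(d_hat.mean()), float(d_hat.var(ddof=1))
        a_prior = (2 * d_s2 + d_m**2) / d_s2 if d_s2 > 0 else 100.0
        b_prior = (d_m * d_s2 + d_m**3) / d_s2 if d_s2 > 0 else d_m * 99.0
        g_star, d_star = g_hat.copy(), d_hat.copy()
        for _ in range(100):
            g_new = (nb_i * t2 * g_hat + d_star * g_bar) / (nb_i * t2 + d_star)
            sum2 = ((s[:, cols] - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * sum2 + b_prior) / (nb_i / 2 + a_prior - 1)
            if (np.abs(g_new - g_star).max() < 1e-8
                    and np.abs(d_new - d_star).max() < 1e-8):
                g_star, d_star = g_new, d_new
                break
            g_star, d_star = g_new, d_new
        adjusted[:, cols] = (s[:, cols] - g_star[:, None]) / np.sqrt(d_star)[:, None]

    out = adjusted * np.sqrt(var_pooled)[:, None] + stand_mean
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def select_most_variable(beta: pd.DataFrame, k: int) -> list[str]:
    """Top-k probes by across-sample beta variance, ties broken by
    lexicographic probe id (deterministic)."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(beta):
        raise ValueError("k exceeds the number of probes")
    var = beta.var(axis=1, ddof=1)
    order = sorted(beta.index, key=lambda p: (-var[p], p))
    return [str(p) for p in order[:k]]
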