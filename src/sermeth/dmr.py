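"""Region-level differential methylation by bump hunting.

Probes are clustered by genomic proximity (inter-probe gap <= maxgap,
250 bp by default), per-probe group effects are thresholded at a global
cutoff K (a quantile of |effect|), and maximal runs of >= 2 consecutive
same-sign exceedances within a cluster become candidate regions scored
by their area (sum of |effect| over the run). Significance comes from
group-label permutations: each permutation regenerates null regions with
the SAME cutoff, giving a pooled null of region areas (per-region p) and
a null of per-permutation maximum areas (family-wise error rate). A
region is reported significant when FWER < 0.10, p < 0.01 and it spans
at least two adjacent CpG sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

__all__ = [
    "cluster_probes",
    "candidate_bumps",
    "permutation_fwer",
    "annotate_dmrs",
    "DmrResult",
]


def cluster_probes(ann: pd.DataFrame, maxgap: int = 250) -> pd.DataFrame:
    """Assign maximal proximity clusters.

    Returns a copy of the annotation sorted by (chrom, pos) with an
    integer ``cluster`` column; a new cluster starts at every chromosome
    change or whenever the gap to the previous probe exceeds ``maxgap``
    (a gap of exactly ``maxgap`` stays in the cluster).
    """
    out = ann.sort_values(["chrom", "pos"], kind="mergesort").copy()
    chrom = out["chrom"].to_numpy()
    pos = out["pos"].to_numpy()
    brk = np.ones(len(out), dtype=bool)
    if len(out) > 1:
        brk[1:] = (chrom[1:] != chrom[:-1]) | ((pos[1:] - pos[:-1]) > maxgap)
    out["cluster"] = np.cumsum(brk) - 1
    return out


def _runs(cluster: np.ndarray, effect: np.ndarray, cutoff: float):
    """Maximal same-sign exceedance runs of length >= 2 within clusters.

    Returns (start index, length, sign, area) arrays; area is the sum of
    |effect| over the run.
    """
    n = len(effect)
    s = np.zeros(n, dtype=np.int8)
    s[effect > cutoff] = 1
    s[effect < -cutoff] = -1
    brk = np.ones(n, dtype=bool)
    if n > 1:
        brk[1:] = (cluster[1:] != cluster[:-1]) | (s[1:] != s[:-1])
    starts = np.flatnonzero(brk)
    lengths = np.diff(np.append(starts, n))
    sign = s[starts]
    areas = np.add.reduceat(np.abs(effect), starts)
    keep = (sign != 0) & (lengths >= 2)
    return starts[keep], lengths[keep], sign[keep], areas[keep]


def candidate_bumps(
    clustered_ann: pd.DataFrame,
    effects: pd.Series,
    cutoff_quantile: float = 0.99,
    cutoff: float | None = None,
) -> tuple[pd.DataFrame, float]:
    """Extract candidate regions from per-probe effects.

    ``clustered_ann`` must carry the ``cluster`` column from
    :func:`cluster_probes`; ``effects`` is aligned on its probe ids. When
    ``cutoff`` is not given it is set to the ``cutoff_quantile`` of
    |effect| over all probes. Returns (candidates, cutoff used).
    """
    eff = effects.loc[clustered_ann.index].to_numpy(dtype=float)
    if cutoff is None:
        cutoff = float(np.quantile(np.abs(eff), cutoff_quantile))
    if np.ptp(eff) == 0:
        warnings.warn("degenerate effects (all equal): no candidate regions")
        return _empty_candidates(), cutoff
    starts, lengths, sign, areas = _runs(
        clustered_ann["cluster"].to_numpy(), eff, cutoff
    )
    pos = clustered_ann["pos"].to_numpy()
    chrom = clustered_ann["chrom"].to_numpy()
    ids = clustered_ann.index.to_numpy()
    rows = []
    for st, ln, sg, ar in zip(starts, lengths, sign, areas):
        sl = slice(st, st + ln)
        rows.append(
            {
                "chrom": chrom[st],
                "start": int(pos[sl].min()),
                "end": int(pos[sl].max()),
                "length_bp": int(pos[sl].max() - pos[sl].min() + 1),
                "n_probes": int(ln),
                "direction": "hyper" if sg > 0 else "hypo",
                "area": float(ar),
                "probe_ids": ";".join(map(str, ids[sl])),
            }
        )
    if not rows:
        return _empty_candidates(), cutoff
    return pd.DataFrame(rows), cutoff


def _empty_candidates() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["chrom", "start", "end", "length_bp", "n_probes",
                 "direction", "area", "probe_ids"]
    )


@dataclass
class DmrResult:
    """Permutation-assessed regions plus the null metadata."""

    table: pd.DataFrame
    cutoff: float
    n_permutations: int
    enumerated: bool


def permutation_fwer(
    m: pd.DataFrame,
    case_cols: list[str],
    control_cols: list[str],
    ann: pd.DataFrame,
    beta: pd.DataFrame | None = None,
    B: int = 100,
    seed: int = 0,
    maxgap: int = 250,
    cutoff_quantile: float = 0.99,
    fwer_thresh: float = 0.10,
    p_thresh: float = 0.01,
) -> DmrResult:
    """Bump hunting with permutation-based region significance.

    Per-probe effects are case-minus-control mean differences on the M
    scale. Group labels are permuted across the contrast's samples; each
    permutation re-extracts candidate regions with the same cutoff K.
    Region p = (1 + #null regions with area >= observed) /
    (1 + total null regions); FWER = (1 + #permutations whose maximum
    null area >= observed) / (1 + B). When the contrast admits no more
    than ``B`` distinct label assignments, all of them (minus the
    observed one) are enumerated instead of sampled. The +1 corrections
    keep estimates away from zero at finite B.
    """
    if B < 1:
        raise ValueError("need B >= 1 permutations")
    cols = list(case_cols) + list(control_cols)
    clustered = cluster_probes(ann.loc[m.index], maxgap=maxgap)
    X = m.loc[clustered.index, cols].to_numpy(dtype=float)
    n, n1 = len(cols), len(case_cols)
    cluster_arr = clustered["cluster"].to_numpy()

    def effect_for(case_idx: np.ndarray) -> np.ndarray:
        w = np.full(n, -1.0 / (n - n1))
        w[case_idx] = 1.0 / n1
        return X @ w

    observed_idx = np.arange(n1)
    eff_obs = effect_for(observed_idx)
    candidates, cutoff = candidate_bumps(
        clustered, pd.Series(eff_obs, index=clustered.index),
        cutoff_quantile=cutoff_quantile,
    )

    rng = np.random.default_rng(seed)
    # a labeling and its complement give mirrored effects and identical
    # areas, so balanced contrasts are enumerated over unordered partitions
    balanced = 2 * n1 == n
    total = comb(n - 1, n1 - 1) if balanced else comb(n, n1)
    obs_set = set(observed_idx.tolist())
    if total - 1 <= B:
        if balanced:
            pool_combos = [(0, *c) for c in combinations(range(1, n), n1 - 1)]
        else:
            pool_combos = list(combinations(range(n), n1))
        labelings = [np.array(c) for c in pool_combos if set(c) != obs_set]
        enumerated = True
        if total - 1 < B:
            warnings.warn(
                f"only {total - 1} distinct label permutations exist; "
                "enumerating all of them"
            )
    else:
        labelings = [rng.choice(n, size=n1, replace=False) for _ in range(B)]
        enumerated = False

    null_areas: list[np.ndarray] = []
    perm_max = np.zeros(len(labelings))
    for k, lab in enumerate(labelings):
        _, _, _, areas = _runs(cluster_arr, effect_for(lab), cutoff)
        null_areas.append(areas)
        perm_max[k] = areas.max() if areas.size else 0.0
    pooled = np.concatenate(null_areas) if null_areas else np.array([])
    B_eff = len(labelings)

    tab = candidates.copy()
    if len(tab):
        obs_areas = tab["area"].to_numpy()
        tab["p"] = [(1 + np.count_nonzero(pooled >= a)) / (1 + pooled.size)
                    for a in obs_areas]
        tab["fwer"] = [(1 + np.count_nonzero(perm_max >= a)) / (1 + B_eff)
                       for a in obs_areas]
        if beta is not None:
            db = (beta[list(case_cols)].mean(axis=1)
                  - beta[list(control_cols)].mean(axis=1))
            tab["mean_delta_beta"] = [
                float(db.loc[pids.split(";")].mean()) for pids in tab["probe_ids"]
            ]
        tab["significant"] = ((tab["fwer"] < fwer_thresh) & (tab["p"] < p_thresh)
                              & (tab["n_probes"] >= 2))
        tab = tab.sort_values("area", ascending=False).reset_index(drop=True)
    else:
        for c in ("p", "fwer", "mean_delta_beta"):
            tab[c] = pd.Series(dtype=float)
        tab["significant"] = pd.Series(dtype=bool)
    return DmrResult(table=tab, cutoff=cutoff, n_permutations=B_eff,
                     enumerated=enumerated)


def annotate_dmrs(dmrs: pd.DataFrame, ann: pd.DataFrame) -> pd.DataFrame:
    """Attach gene / regulatory feature / CGI columns to regions.

    Gene symbols are the union over member probes; feature and CGI
    relation are majority votes with ties resolved toward the first
    member probe's value.
    """
    out = dmrs.copy()
    genes_col, feat_col, cgi_col = [], [], []
    for pids in out["probe_ids"]:
        members = pids.split(";")
        missing = [p for p in members if p not in ann.index]
        if missing:
            raise KeyError(f"DMR probes missing from annotation: {missing}")
        sub = ann.loc[members]
        genes = []
        for g in sub["genes"]:
            genes.extend(x for x in str(g).split(";") if x)
        genes_col.append(";".join(dict.fromkeys(genes)))
        feat_col.append(_majority(sub["feature"]))
        cgi_col.append(_majority(sub["cgi_relation"]))
    out["genes"] = genes_col
    out["feature"] = feat_col
    out["cgi_relation"] = cgi_col
    return out


def _majority(values: pd.Series) -> str:
    counts = values.value_counts()
    top = counts.max()
    winners = set(counts[counts == top].index)
    for v in values:  # tie -> first probe's value
        if v in winners:
            return str(v)
    return str(values.iloc[0])
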