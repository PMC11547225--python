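"""Synthetic serum-methylome cohort generator.

Emulates the data structure of a pooled cfDNA methylation-array study of
the colorectal serrated pathway: individual-level beta values per
pathology group, equal-mass pooling of sex-balanced groups of
individuals, slide (batch) effects on the M scale, spatially clustered
differential regions, per-probe detection statistics, and MS-qPCR plates
whose Cq values follow a log-linear standard-curve model.

Every downstream stage of the package is testable against the ground
truth this module records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .config import (
    CGI_RELATIONS,
    FEATURES,
    ConfigError,
    QpcrSimConfig,
    SimulationConfig,
)

ARRAYS_PER_SLIDE = 8  # EPIC BeadChips carry 8 arrays per slide

_CGI_P = (0.30, 0.20, 0.10, 0.40)
_FEATURE_P = (0.10, 0.08, 0.07, 0.05, 0.40, 0.05, 0.25)
# baseline beta distributions: CGI probes skew unmethylated, opensea methylated
_BASELINE_AB = {"CGI": (1.5, 10.0), "shore": (2.0, 5.0), "shelf": (4.0, 3.0),
                "opensea": (10.0, 1.8)}


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort (for recovery tests)."""

    true_dmp_ids: list[str]
    true_dmr_intervals: pd.DataFrame  # chrom, start, end, direction, delta_beta, n_probes, probe_ids
    group_means: pd.DataFrame  # probes x groups, mean beta
    batch: pd.Series  # pool id -> slide
    affected_groups: tuple[str, ...]


@dataclass
class DetectionStats:
    """Per-probe, per-sample detection p-values and bead counts."""

    detection_p: pd.DataFrame
    bead_count: pd.DataFrame


def _simulate_manifest(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_probes
    probe_ids = np.array([f"cg{i:08d}" for i in range(n)])

    # ~2% of probes live on sex chromosomes, the rest on 22 autosomes
    n_sex = max(2, int(round(0.02 * n)))
    n_auto = n - n_sex
    bounds = np.linspace(0, n_auto, 23).astype(int)
    chrom = np.empty(n, dtype=object)
    for c in range(22):
        chrom[bounds[c]:bounds[c + 1]] = f"chr{c + 1}"
    chrom[n_auto:n_auto + n_sex // 2] = "chrX"
    chrom[n_auto + n_sex // 2:] = "chrY"

    # inter-probe gaps: a mixture of tight (clusterable, <= 250 bp) and wide
    tight = rng.random(n) < 0.35
    gaps = np.where(tight, rng.integers(30, 251, size=n), rng.integers(300, 5001, size=n))
    pos = np.empty(n, dtype=np.int64)
    start = 0
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        pos[idx] = 10_000 + np.cumsum(gaps[idx])
        start += len(idx)

    cgi = rng.choice(CGI_RELATIONS, size=n, p=_CGI_P)
    feature = rng.choice(FEATURES, size=n, p=_FEATURE_P)
    # neighbouring probes share genes; intergenic probes have none
    gene_block = np.arange(n) // 5
    genes = np.array([f"GENE{b:05d}" for b in gene_block], dtype=object)
    second = rng.random(n) < 0.05
    genes = np.where(second, genes + ";" + np.array([f"GENE{b + 1:05d}" for b in gene_block]),
                     genes)
    genes[feature == "intergenic"] = ""

    ann = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "cgi_relation": cgi,
            "feature": feature,
            "genes": genes,
            "cross_reactive": rng.random(n) < 0.01,
            "snp": rng.random(n) < 0.01,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    ann["sex_chrom"] = ann["chrom"].isin(["chrX", "chrY"])
    return ann


def _carve_dmr_runs(ann: pd.DataFrame, cfg: SimulationConfig,
                    rng: np.random.Generator) -> list[np.ndarray]:
    """Pick disjoint autosomal probe runs and force tight spacing inside them.

    The run is isolated by widening the flanking gaps beyond 250 bp so the
    injected region coincides with a maximal probe cluster.
    """
    n = len(ann)
    eligible = ~(ann["cross_reactive"] | ann["snp"] | ann["sex_chrom"]).to_numpy()
    chrom = ann["chrom"].to_numpy()
    pos = ann["pos"].to_numpy().copy()
    taken = np.zeros(n, dtype=bool)
    runs: list[np.ndarray] = []
    max_len = cfg.dmr_n_probes[1]
    attempts = 0
    while len(runs) < cfg.n_dmr_true:
        attempts += 1
        if attempts > 1000 * max(1, cfg.n_dmr_true):
            raise ConfigError("could not place requested DMR runs; increase n_probes")
        k = int(rng.integers(cfg.dmr_n_probes[0], cfg.dmr_n_probes[1] + 1))
        s = int(rng.integers(1, n - max_len - 1))
        idx = np.arange(s, s + k)
        if (not eligible[idx].all() or taken[max(0, s - 1): s + k + 1].any()
                or len(set(chrom[idx])) != 1 or chrom[s - 1] != chrom[s]
                or s + k >= n or chrom[s + k] != chrom[s]):
            continue
        gaps = rng.integers(cfg.dmr_span_gap_bp[0], cfg.dmr_span_gap_bp[1] + 1, size=k - 1)
        pos[idx[1:]] = pos[s] + np.cumsum(gaps)
        # isolate: push the next probe on the chromosome beyond maxgap
        shift = (pos[idx[-1]] + int(rng.integers(400, 2001))) - pos[s + k]
        same = np.flatnonzero((chrom == chrom[s]) & (np.arange(n) >= s + k))
        if shift > 0:
            pos[same] += shift
        taken[idx] = True
        runs.append(idx)
    ann["pos"] = pos
    return runs


def simulate_individuals(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate individual-level beta values for a pooled-cohort design.

    Returns ``(beta, annotation, sample_sheet, truth)``. Baseline beta is
    bimodal across the array (CGI probes skew low, opensea high); injected
    positions shift the affected groups' mean beta by a signed delta drawn
    from ``config.effect_size_beta``; injected regions shift all member
    probes coherently. Individual values are Beta-distributed around group
    means with precision ``noise_kappa``. Deterministic given
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ann = _simulate_manifest(config, rng)
    dmr_runs = _carve_dmr_runs(ann, config, rng)
    n = config.n_probes
    groups = list(config.groups)

    a = np.array([_BASELINE_AB[c][0] for c in ann["cgi_relation"]])
    b = np.array([_BASELINE_AB[c][1] for c in ann["cgi_relation"]])
    mu0 = np.clip(rng.beta(a, b), 0.02, 0.98)

    group_means = pd.DataFrame(
        np.tile(mu0[:, None], (1, len(groups))), index=ann.index, columns=groups
    )
    affected = [g for g in groups if g in config.affected_groups]

    # isolated DMPs, away from the injected regions and from masked probes
    in_run = np.zeros(n, dtype=bool)
    for idx in dmr_runs:
        in_run[idx] = True
    eligible = np.flatnonzero(
        ~(ann["cross_reactive"] | ann["snp"] | ann["sex_chrom"]).to_numpy() & ~in_run
    )
    dmp_idx = rng.choice(eligible, size=min(config.n_dmp_true, len(eligible)), replace=False)
    lo, hi = config.effect_size_beta
    for i in dmp_idx:
        delta = float(rng.uniform(lo, hi)) * (1 if rng.random() < 0.5 else -1)
        if not (0.02 <= mu0[i] + delta <= 0.98):
            delta = -delta
        delta = float(np.clip(mu0[i] + delta, 0.02, 0.98) - mu0[i])
        group_means.iloc[i, [groups.index(g) for g in affected]] = mu0[i] + delta

    dmr_rows = []
    for idx in dmr_runs:
        # region probes get intermediate baselines so the coherent shift is
        # not truncated by the [0,1] bounds at any member probe
        mu0[idx] = rng.uniform(0.25, 0.75, size=len(idx))
        group_means.iloc[idx, :] = np.tile(mu0[idx][:, None], (1, len(groups)))
        direction = "hyper" if rng.random() < 0.5 else "hypo"
        delta = float(rng.uniform(lo, hi)) * (1 if direction == "hyper" else -1)
        shifted = np.clip(mu0[idx] + delta, 0.02, 0.98)
        cols = [groups.index(g) for g in affected]
        group_means.iloc[idx, cols] = np.tile(shifted[:, None], (1, len(cols)))
        dmr_rows.append(
            {
                "chrom": ann["chrom"].iloc[idx[0]],
                "start": int(ann["pos"].iloc[idx[0]]),
                "end": int(ann["pos"].iloc[idx[-1]]),
                "direction": direction,
                "delta_beta": delta,
                "n_probes": len(idx),
                "probe_ids": ";".join(ann.index[idx]),
            }
        )
    dmr_df = pd.DataFrame(
        dmr_rows, columns=["chrom", "start", "end", "direction", "delta_beta",
                           "n_probes", "probe_ids"]
    )

    # sample sheet: sex-balanced groups, two centres, pool pre-allocation
    rows = []
    pool_counter = 0
    for g in groups:
        n_ind = config.n_individuals_per_group.get(g, 0)
        for j in range(n_ind):
            rows.append(
                {
                    "sample_id": f"{g}_ind{j:03d}",
                    "group": g,
                    "sex": "M" if j % 2 == 0 else "F",
                    "age": int(np.clip(round(rng.normal(60, 8)), 40, 85)),
                    "center": f"center{j % 2 + 1}",
                }
            )
    sheet = pd.DataFrame(rows).set_index("sample_id")
    pools = assign_pools(sheet, config.pool_size)
    sheet["pool"] = pools
    # pools are spread round-robin over slides, emulating a design that
    # mixes pathology groups within each BeadChip to avoid confounding
    pool_list = [p for p in pd.unique(pools) if p]
    n_slides = max(1, -(-len(pool_list) // ARRAYS_PER_SLIDE))
    slide_of_pool = {}
    for p in pool_list:
        slide_of_pool[p] = f"slide{pool_counter % n_slides + 1}"
        pool_counter += 1
    sheet["batch"] = sheet["pool"].map(slide_of_pool).fillna("")

    mu = group_means[sheet["group"]].to_numpy()  # probes x individuals
    mu = np.clip(mu, 1e-3, 1 - 1e-3)
    kappa = config.noise_kappa
    beta_vals = rng.beta(mu * kappa, (1 - mu) * kappa)
    beta = pd.DataFrame(beta_vals, index=ann.index, columns=sheet.index)

    truth = SyntheticTruth(
        true_dmp_ids=[str(p) for p in ann.index[dmp_idx]],
        true_dmr_intervals=dmr_df,
        group_means=group_means,
        batch=pd.Series(slide_of_pool, name="batch"),
        affected_groups=tuple(affected),
    )
    return beta, ann, sheet, truth


def assign_pools(sheet: pd.DataFrame, pool_size: int) -> pd.Series:
    """Allocate individuals to sex-balanced pools within each group.

    Members are stratified on (center, age) before filling so pools are
    matched; individuals left over after filling whole pools get an empty
    pool id. Raises if any group is smaller than ``pool_size``.
    """
    half = pool_size // 2
    pool = pd.Series("", index=sheet.index, dtype=object)
    for g, sub in sheet.groupby("group", sort=False):
        if len(sub) < pool_size:
            raise ValueError(f"group {g!r} has {len(sub)} members < pool_size {pool_size}")
        males = sub[sub["sex"] == "M"].sort_values(["center", "age"]).index
        females = sub[sub["sex"] == "F"].sort_values(["center", "age"]).index
        n_pools = min(len(males), len(females)) // half
        for j in range(n_pools):
            pid = f"{g}_pool{j + 1}"
            pool[males[j * half:(j + 1) * half]] = pid
            pool[females[j * half:(j + 1) * half]] = pid
    return pool


def pool_samples(
    individuals: pd.DataFrame,
    sheet: pd.DataFrame,
    pool_size: int = 10,
    *,
    batch_effect_sd: float = 0.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pool individuals with equal DNA mass: pooled beta = member mean.

    Slide (batch) effects, when requested, are additive on the M scale and
    shared by all probes on a slide with per-probe Gaussian scatter;
    measurement noise is Beta-distributed with SD ``noise_sd`` on the beta
    scale. With both set to 0 the pooled value is the exact member mean.
    """
    from .preprocess import beta_to_m, m_to_beta

    if rng is None:
        rng = np.random.default_rng()
    if "pool" not in sheet.columns or (sheet["pool"] == "").all():
        sheet = sheet.copy()
        sheet["pool"] = assign_pools(sheet, pool_size)
    pool_ids = [p for p in pd.unique(sheet["pool"]) if p]
    cols, rows = {}, []
    slides = sheet.get("batch")
    slide_shift: dict[str, np.ndarray] = {}
    for pid in pool_ids:
        members = sheet.index[sheet["pool"] == pid]
        pooled = individuals[members].mean(axis=1).to_numpy()
        slide = str(slides[members[0]]) if slides is not None else ""
        if batch_effect_sd > 0 and slide:
            if slide not in slide_shift:
                gamma = rng.normal(0.0, batch_effect_sd)
                slide_shift[slide] = gamma + rng.normal(
                    0.0, batch_effect_sd / 2, size=len(individuals)
                )
            m = beta_to_m(pd.DataFrame({pid: pooled}, index=individuals.index))
            pooled = m_to_beta(m + slide_shift[slide][:, None])[pid].to_numpy()
        if noise_sd > 0:
            mu = np.clip(pooled, 1e-3, 1 - 1e-3)
            kap = np.maximum(mu * (1 - mu) / noise_sd**2 - 1, 2.0)
            pooled = rng.beta(mu * kap, (1 - mu) * kap)
        cols[pid] = pooled
        grp = sheet.loc[members, "group"].iloc[0]
        rows.append(
            {
                "sample_id": pid,
                "group": grp,
                "sex": "both",
                "age": float(sheet.loc[members, "age"].mean()),
                "center": sheet.loc[members, "center"].mode().iloc[0],
                "batch": slide,
                "members": ";".join(members),
            }
        )
    pooled_beta = pd.DataFrame(cols, index=individuals.index)
    pool_sheet = pd.DataFrame(rows).set_index("sample_id")
    return pooled_beta, pool_sheet


def simulate_detection_stats(
    beta: pd.DataFrame,
    fail_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> DetectionStats:
    """Simulate detection p-values and bead counts for a measured matrix.

    A ``fail_rate`` fraction of probes is flagged: the flagged probe gets
    either a detection p above 0.01 or a bead count below 3 in one random
    sample, so it fails the standard quality filter.
    """
    if not 0 <= fail_rate < 1:
        raise ValueError("fail_rate must lie in [0, 1)")
    if rng is None:
        rng = np.random.default_rng()
    n, s = beta.shape
    det_p = pd.DataFrame(rng.uniform(0, 0.005, size=(n, s)),
                         index=beta.index, columns=beta.columns)
    beads = pd.DataFrame(rng.integers(5, 31, size=(n, s)),
                         index=beta.index, columns=beta.columns)
    flagged = np.flatnonzero(rng.random(n) < fail_rate)
    for i in flagged:
        j = int(rng.integers(0, s))
        if rng.random() < 0.5:
            det_p.iloc[i, j] = rng.uniform(0.02, 0.5)
        else:
            beads.iloc[i, j] = int(rng.integers(0, 3))
    return DetectionStats(detection_p=det_p, bead_count=beads)


def simulate_qpcr_plate(
    true_methylation_pct: Mapping[str, float],
    config: QpcrSimConfig | None = None,
    rng: np.random.Generator | None = None,
    input_pct: Mapping[str, float] | None = None,
    target: str = "DMR",
) -> pd.DataFrame:
    """Simulate a long-format MS-qPCR plate for one methylation target.

    Cq = intercept + slope * log10(%) + Normal(0, cq_sd) per replicate;
    0% methylation (and the no-template control) emit undetermined Cq
    (NaN). The plate carries the standard-curve dilution series for the
    target and for the ACTB input assay, fully methylated (FMC) and fully
    unmethylated (FUC) controls, and an ACTB well set per sample.
    """
    cfg = config or QpcrSimConfig()
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng()
    for s, pct in true_methylation_pct.items():
        if pct < 0:
            raise ValueError(f"negative methylation percentage for sample {s!r}")
    input_pct = dict(input_pct or {})

    def cq_of(pct: float) -> float:
        if pct <= 0:
            return np.nan
        cq = cfg.intercept + cfg.slope * np.log10(pct) + rng.normal(0.0, cfg.cq_sd)
        return np.nan if cq > cfg.undetermined_cq_threshold else float(cq)

    rows = []

    def add(tgt, sample, pct, role, dilution=np.nan):
        for r in range(1, cfg.n_replicates + 1):
            rows.append({"target": tgt, "sample": sample, "replicate": r,
                         "cq": cq_of(pct), "role": role, "dilution_pct": dilution})

    for tgt in (target, "ACTB"):
        for pct in cfg.dilution_points:
            add(tgt, f"STD_{pct:g}", pct, "standard", pct)
        add(tgt, "FMC", 100.0, "fmc")
        add(tgt, "FUC", 0.0 if tgt != "ACTB" else 100.0, "fuc")
        add(tgt, "NTC", 0.0, "ntc")
    for sample, pct in true_methylation_pct.items():
        inp = input_pct.get(sample, 100.0)
        # methylated template scales with the DNA input, so NMP (but not
        # RMP) is invariant to the amount loaded
        add(target, sample, pct * inp / 100.0, "sample")
        add("ACTB", sample, inp, "sample")
    return pd.DataFrame(rows)


def simulate_gene_sets(
    genes: list[str],
    n_sets: int = 200,
    rng: np.random.Generator | None = None,
    size_range: tuple[int, int] = (5, 50),
) -> pd.DataFrame:
    """Generate a synthetic GO-like gene-set collection.

    Returns a frame with columns ``set_id``, ``name``, ``branch``
    (BP/CC/MF) and ``members`` (semicolon-joined gene symbols) suitable
    for writing as GMT. The sets are random draws from the supplied gene
    universe — synthetic stand-ins with the size distribution of curated
    ontology terms, not real annotations.
    """
    if rng is None:
        rng = np.random.default_rng()
    genes = list(dict.fromkeys(genes))
    rows = []
    for i in range(n_sets):
        k = int(rng.integers(size_range[0], min(size_range[1], len(genes)) + 1))
        members = rng.choice(genes, size=k, replace=False)
        branch = ("BP", "CC", "MF")[int(rng.integers(0, 3))]
        rows.append({"set_id": f"GO:{i:07d}", "name": f"synthetic term {i}",
                     "branch": branch, "members": ";".join(sorted(members))})
    return pd.DataFrame(rows)
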