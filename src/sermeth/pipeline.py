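"""End-to-end pipeline driver: simulate -> preprocess -> DMPs -> DMRs ->
enrichment -> qPCR -> classification, with a run manifest for
auditability. Identical (config, seed) pairs reproduce every output."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, classify, diffmeth, dmr, io, msqpcr, ontology, preprocess, synthdata
from .config import PipelineConfig

log = logging.getLogger("sermeth")


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    outputs: dict[str, str] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    timestamp: str = ""

    def write(self, path) -> None:
        tmp = Path(str(path) + ".tmp")
        tmp.write_text(json.dumps(self.__dict__, indent=1, default=str))
        tmp.replace(path)  # atomic at run end


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir) -> RunManifest:
    """Execute the full analysis on a simulated cohort.

    Writes every intermediate table under ``outdir`` and returns the run
    manifest (tool version, config hash, per-output checksums, stage
    timings, headline counts).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__,
        config_hash=hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        seed=config.seed,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    def record(name: str, path: Path) -> None:
        manifest.outputs[name] = f"{path.name}:{_sha(path)}"

    t0 = time.time()
    rng = np.random.default_rng(config.seed)
    config.sim.seed = config.seed
    beta_ind, ann, sheet, truth = synthdata.simulate_individuals(config.sim)
    pooled, pool_sheet = synthdata.pool_samples(
        beta_ind, sheet, config.sim.pool_size,
        batch_effect_sd=config.sim.batch_effect_sd,
        noise_sd=config.sim.pool_noise_sd, rng=rng,
    )
    det = synthdata.simulate_detection_stats(pooled, config.detection_fail_rate, rng)
    io.write_beta(pooled, outdir / "beta_pools.tsv")
    io.write_manifest(ann, outdir / "manifest.tsv")
    io.write_sheet(pool_sheet, outdir / "sample_sheet.csv")
    io.write_truth(truth, outdir / "truth.json")
    record("beta", outdir / "beta_pools.tsv")
    record("manifest", outdir / "manifest.tsv")
    record("sheet", outdir / "sample_sheet.csv")
    record("truth", outdir / "truth.json")
    manifest.stage_seconds["simulate"] = round(time.time() - t0, 2)
    log.info("simulated %d probes x %d pools", *pooled.shape)

    t0 = time.time()
    filtered, report = preprocess.filter_probes(pooled, det, ann)
    m = preprocess.beta_to_m(filtered, clip_eps=config.clip_eps)
    if pool_sheet["batch"].nunique() > 1:
        try:
            m = preprocess.combat_adjust(m, pool_sheet["batch"], pool_sheet["group"])
        except ValueError as e:
            log.warning("batch adjustment skipped: %s", e)
    beta_adj = preprocess.m_to_beta(m)
    io.write_beta(beta_adj, outdir / "beta_filtered.tsv")
    (outdir / "filter_report.json").write_text(json.dumps(report.__dict__, indent=1))
    record("beta_filtered", outdir / "beta_filtered.tsv")
    record("filter_report", outdir / "filter_report.json")
    manifest.counts["probes_filtered_in"] = report.n_input
    manifest.counts["probes_filtered_out"] = report.n_output
    manifest.stage_seconds["preprocess"] = round(time.time() - t0, 2)
    log.info("filter: %d -> %d probes (%s)", report.n_input, report.n_output,
             report.removed)

    groups = pool_sheet["group"]
    n_dmps = 0
    n_dmrs = 0
    first_dmps: pd.Index | None = None
    t0 = time.time()
    for case, control in config.contrasts:
        case_cols = list(groups.index[groups == case])
        control_cols = list(groups.index[groups == control])
        if len(case_cols) < 2 or len(control_cols) < 2:
            log.warning("contrast %s vs %s skipped: need >= 2 pools per side",
                        case, control)
            continue
        tag = f"{case}_vs_{control}".replace("-", "")
        res = diffmeth.dmp_test(m, beta_adj, case_cols, control_cols,
                                p_thresh=config.p_thresh, db_thresh=config.db_thresh)
        io.write_results(res, outdir / f"dmp_{tag}.tsv")
        record(f"dmp_{tag}", outdir / f"dmp_{tag}.tsv")
        called = res.index[res["call"] != "ns"]
        n_dmps += len(called)
        if first_dmps is None and len(called):
            first_dmps = called
        log.info("%s vs %s: %d DMPs (%d hyper / %d hypo)", case, control,
                 len(called), (res["call"] == "hyper").sum(), (res["call"] == "hypo").sum())

        result = dmr.permutation_fwer(
            m, case_cols, control_cols, ann.loc[m.index], beta=beta_adj,
            B=config.n_permutations, seed=int(rng.integers(2**31)),
            maxgap=config.maxgap, cutoff_quantile=config.cutoff_quantile,
            fwer_thresh=config.fwer_thresh, p_thresh=config.p_thresh,
        )
        table = dmr.annotate_dmrs(result.table, ann) if len(result.table) else result.table
        io.write_results(table, outdir / f"dmr_{tag}.tsv", index=False)
        record(f"dmr_{tag}", outdir / f"dmr_{tag}.tsv")
        sig = table[table["significant"]] if len(table) else table
        if len(sig):
            io.write_dmr_bed(sig, outdir / f"dmr_{tag}.bed")
            record(f"dmr_bed_{tag}", outdir / f"dmr_{tag}.bed")
        n_dmrs += len(sig)
    manifest.counts["dmps_total"] = int(n_dmps)
    manifest.counts["dmrs_significant_total"] = int(n_dmrs)
    manifest.stage_seconds["differential"] = round(time.time() - t0, 2)

    t0 = time.time()
    if first_dmps is not None and len(first_dmps) >= 3:
        enr = diffmeth.annotation_enrichment(first_dmps, ann.loc[m.index])
        io.write_results(enr, outdir / "annotation_enrichment.tsv", index=False)
        record("annotation_enrichment", outdir / "annotation_enrichment.tsv")
        dm_genes, probe_counts = ontology.probes_to_genes(first_dmps, ann)
        if dm_genes:
            sets_frame = synthdata.simulate_gene_sets(
                list(probe_counts.index), n_sets=200, rng=rng
            )
            sets = ontology.gene_sets_from_frame(sets_frame)
            go = ontology.wallenius_enrichment(
                dm_genes, set(probe_counts.index), probe_counts, sets
            )
            io.write_results(go, outdir / "go_enrichment.tsv", index=False)
            record("go_enrichment", outdir / "go_enrichment.tsv")
            if go["significant"].sum() >= 2:
                sim, Z = ontology.jaccard_term_similarity(go, sets, dm_genes)
                (outdir / "go_terms.nwk").write_text(
                    io.linkage_to_newick(Z, list(sim.index)))
                record("go_tree", outdir / "go_terms.nwk")
    manifest.stage_seconds["enrichment"] = round(time.time() - t0, 2)

    # targeted MS-qPCR panel on an individual-level serum cohort
    t0 = time.time()
    qrng = np.random.default_rng(config.seed + 1)
    panel_groups = {"NCF": 20, "LR-SL": 15, "HR-HP": 15, "HR-SP": 20, "SAC": 10}
    level = {"NCF": 2.0, "LR-SL": 4.0, "HR-HP": 25.0, "HR-SP": 35.0, "SAC": 55.0}
    samples, sample_group = {}, {}
    for g, count in panel_groups.items():
        for i in range(count):
            sid = f"{g}_serum{i:02d}"
            samples[sid] = float(np.clip(qrng.normal(level[g], level[g] * 0.4), 0.0, 100.0))
            sample_group[sid] = g
    plate = synthdata.simulate_qpcr_plate(samples, config.qpcr, qrng, target="DMR7")
    io.write_plate(plate, outdir / "plate_DMR7.csv")
    record("plate", outdir / "plate_DMR7.csv")
    measurements, curves = msqpcr.quantify_plate(plate, "DMR7")
    io.write_results(measurements, outdir / "marker_measurements.tsv", index=False)
    record("measurements", outdir / "marker_measurements.tsv")
    (outdir / "standard_curves.json").write_text(json.dumps(
        {t: {"slope": c.slope, "intercept": c.intercept, "r2": c.r2,
             "efficiency": c.efficiency, "qc_pass": c.qc_pass}
         for t, c in curves.items()}, indent=1))
    record("curves", outdir / "standard_curves.json")
    manifest.stage_seconds["qpcr"] = round(time.time() - t0, 2)

    t0 = time.time()
    feats = measurements.set_index("sample_id")[["log_nmp"]].rename(
        columns={"log_nmp": "DMR7"})
    serum_sheet = pd.DataFrame({"group": pd.Series(sample_group)})
    spec = classify.ContrastSpec(
        name="NSN_vs_HRSL",
        positive=frozenset({"HR-HP", "HR-SP"}),
        negative=frozenset({"NCF", "LR-SL"}),
        markers=("DMR7",),
    )
    roc = classify.evaluate_contrast(feats, serum_sheet, spec)
    summary = pd.DataFrame([{
        "contrast": spec.name, "auc": roc.auc,
        "auc_lo": roc.auc_ci[0], "auc_hi": roc.auc_ci[1],
        "cutoff": roc.cutoff,
        "sensitivity_pct": 100 * roc.sensitivity,
        "specificity_pct": 100 * roc.specificity,
    }])
    io.write_results(summary, outdir / "classification.tsv", index=False)
    record("classification", outdir / "classification.tsv")
    manifest.counts["classification_auc_x1000"] = int(round(roc.auc * 1000))
    manifest.stage_seconds["classify"] = round(time.time() - t0, 2)

    manifest.write(outdir / "run_manifest.json")
    return manifest
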