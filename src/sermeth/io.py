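"""File formats: TSV/CSV matrices, BED, GMT, Newick, qPCR plate tables.

Dialects: tab-separated matrices with a header row and the probe id as
row key, '.'-decimal numbers, the string ``Undetermined`` as the Cq
sentinel in plate CSVs, BED output 0-based half-open while every
internal and report coordinate is 1-based inclusive (array-manifest
convention).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthdata import DetectionStats, SyntheticTruth

UNDETERMINED = "Undetermined"


# -- matrices -------------------------------------------------------------

def write_beta(beta: pd.DataFrame, path) -> None:
    beta.to_csv(path, sep="\t", index_label="probe_id")


def read_beta(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id")


def write_manifest(ann: pd.DataFrame, path) -> None:
    out = ann.copy()
    for c in ("cross_reactive", "snp", "sex_chrom"):
        out[c] = out[c].astype(int)
    out.to_csv(path, sep="\t", index_label="probe_id")


def read_manifest(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col="probe_id", keep_default_na=False,
                      dtype={"genes": str})
    for c in ("cross_reactive", "snp", "sex_chrom"):
        ann[c] = ann[c].astype(bool)
    return ann


def write_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, index_label="sample_id")


def read_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id", keep_default_na=False)


def write_detection(det: DetectionStats, prefix) -> None:
    prefix = str(prefix)
    det.detection_p.to_csv(prefix + ".detp.tsv", sep="\t", index_label="probe_id")
    det.bead_count.to_csv(prefix + ".beads.tsv", sep="\t", index_label="probe_id")


def read_detection(prefix) -> DetectionStats:
    prefix = str(prefix)
    return DetectionStats(
        detection_p=pd.read_csv(prefix + ".detp.tsv", sep="\t", index_col="probe_id"),
        bead_count=pd.read_csv(prefix + ".beads.tsv", sep="\t", index_col="probe_id"),
    )


def write_results(frame: pd.DataFrame, path, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", index=index,
                 index_label="probe_id" if index else None)


# -- truth ----------------------------------------------------------------

def write_truth(truth: SyntheticTruth, path) -> None:
    payload = {
        "true_dmp_ids": truth.true_dmp_ids,
        "true_dmr_intervals": truth.true_dmr_intervals.to_dict(orient="records"),
        "batch": truth.batch.to_dict(),
        "affected_groups": list(truth.affected_groups),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth_intervals(path) -> pd.DataFrame:
    payload = json.loads(Path(path).read_text())
    return pd.DataFrame(payload["true_dmr_intervals"])


# -- qPCR plates ----------------------------------------------------------

def write_plate(plate: pd.DataFrame, path) -> None:
    out = plate.copy()
    out["cq"] = out["cq"].map(lambda v: UNDETERMINED if v != v else f"{v:.6g}")
    out.to_csv(path, index=False)


def read_plate(path) -> pd.DataFrame:
    plate = pd.read_csv(path, keep_default_na=False,
                        dtype={"sample": str, "target": str})
    plate["cq"] = pd.to_numeric(plate["cq"].replace(UNDETERMINED, np.nan),
                                errors="coerce")
    plate["dilution_pct"] = pd.to_numeric(plate["dilution_pct"], errors="coerce")
    return plate


# -- BED ------------------------------------------------------------------

def write_probe_bed(ann: pd.DataFrame, probe_ids, path, calls=None) -> None:
    """Probes as BED intervals: 1-based position p becomes [p-1, p)."""
    lines = []
    for i, pid in enumerate(probe_ids):
        row = ann.loc[pid]
        name = pid if calls is None else f"{pid}:{calls[i]}"
        lines.append(f"{row['chrom']}\t{int(row['pos']) - 1}\t{int(row['pos'])}\t{name}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_dmr_bed(dmrs: pd.DataFrame, path) -> None:
    lines = [
        f"{r.chrom}\t{int(r.start) - 1}\t{int(r.end)}\tDMR{i + 1}:{r.direction}"
        for i, r in enumerate(dmrs.itertuples())
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# -- gene sets ------------------------------------------------------------

def write_gmt(sets, path) -> None:
    """GMT: set id, description, then member genes, tab-separated."""
    lines = [
        "\t".join([gs.set_id, f"{gs.name}|{gs.branch}"] + sorted(gs.members))
        for gs in sets
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_gmt(path) -> list:
    from .ontology import GeneSet

    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        name, _, branch = parts[1].partition("|")
        sets.append(GeneSet(parts[0], name, branch or "BP", frozenset(parts[2:])))
    return sets


# -- trees ----------------------------------------------------------------

def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch
    lengths derived from merge heights."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def node(i: int) -> str:
        if i < n:
            return labels[i]
        a, b, h, _ = Z[i - n]
        left, right = node(int(a)), node(int(b))
        bl_a = h - heights[int(a)]
        bl_b = h - heights[int(b)]
        heights[i] = h
        return f"({left}:{bl_a:.6g},{right}:{bl_b:.6g})"

    return node(n + len(Z) - 1) + ";"
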