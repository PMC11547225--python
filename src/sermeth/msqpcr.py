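"""Targeted MS-qPCR methylation quantification.

Cq values from methylation-specific qPCR are converted to raw
methylation percentages (RMP) through a log-linear standard curve fitted
on dilutions of a fully methylated control, then normalized for DNA
input via an ACTB assay relative to the fully methylated control:

    NMP = (RMP_sample / ACTB_sample) / (RMP_fmc / ACTB_fmc) * 100

NMP is dimensionless (both numerator and denominator are per-input
ratios) and deliberately not capped at 100; downstream analyses work on
log10(NMP + 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "MarkerMeasurement",
    "aggregate_cq",
    "fit_standard_curve",
    "estimate_rmp",
    "normalize_nmp",
    "quantify_plate",
    "compare_groups",
]

EFFICIENCY_MIN = 0.90
R2_MIN = 0.99


@dataclass
class StandardCurve:
    """Log-linear calibration Cq = intercept + slope * log10(%).

    ``efficiency`` = 10^(−1/slope) − 1; 1.0 means perfect doubling each
    cycle. QC passes when efficiency > 0.90 and R² > 0.99.
    """

    target: str
    slope: float
    intercept: float
    r2: float

    @property
    def efficiency(self) -> float:
        return 10 ** (-1.0 / self.slope) - 1.0

    @property
    def qc_pass(self) -> bool:
        return self.slope < 0 and self.efficiency > EFFICIENCY_MIN and self.r2 > R2_MIN


@dataclass
class MarkerMeasurement:
    """Per-sample, per-target methylation readout."""

    sample_id: str
    target: str
    rmp: float
    actb: float
    nmp: float

    @property
    def log_nmp(self) -> float:
        return math.log10(self.nmp + 1.0)


def aggregate_cq(plate: pd.DataFrame) -> pd.DataFrame:
    """Mean Cq per (target, sample) over determined replicates.

    Undetermined replicates (NaN) are dropped; a well set with no
    determined replicate keeps the undetermined sentinel (NaN mean). The
    replicate SD and count are reported for QC.
    """
    grouped = plate.groupby(["target", "sample"], sort=False)["cq"]
    out = grouped.agg(cq="mean", cq_sd="std", n_determined="count")
    out["n_determined"] = out["n_determined"].astype(int)
    return out.reset_index()


def fit_standard_curve(dilution_pct, cq, target: str = "") -> StandardCurve:
    """Least-squares fit of Cq against log10(% methylation)."""
    pct = np.asarray(dilution_pct, dtype=float)
    cq = np.asarray(cq, dtype=float)
    ok = ~np.isnan(cq)
    pct, cq = pct[ok], cq[ok]
    if np.any(pct <= 0):
        raise ValueError("dilution percentages must be positive")
    if len(np.unique(pct)) < 3:
        raise ValueError("need >= 3 distinct dilution points")
    res = stats.linregress(np.log10(pct), cq)
    return StandardCurve(target=target, slope=float(res.slope),
                         intercept=float(res.intercept),
                         r2=float(res.rvalue**2))


def estimate_rmp(cq: float, curve: StandardCurve, allow_qc_fail: bool = False) -> float:
    """Invert the standard curve: RMP = 10^((Cq − intercept)/slope).

    An undetermined Cq (NaN) means no amplification of the methylated
    template and maps to 0%.
    """
    if not curve.qc_pass and not allow_qc_fail:
        raise ValueError(
            f"standard curve for {curve.target or 'target'} failed QC "
            f"(efficiency={curve.efficiency:.3f}, r2={curve.r2:.4f})"
        )
    if cq != cq:  # NaN sentinel
        return 0.0
    return float(10 ** ((cq - curve.intercept) / curve.slope))


def normalize_nmp(rmp_sample: float, actb_sample: float,
                  rmp_fmc: float, actb_fmc: float) -> float:
    """Normalized methylation percentage (input- and run-normalized).

    Raises when the sample has no measurable ACTB input or the fully
    methylated control ratio is non-positive.
    """
    if actb_sample <= 0 or actb_sample != actb_sample:
        raise ValueError("sample has no measurable ACTB input; NMP undefined")
    fmc_ratio = rmp_fmc / actb_fmc if actb_fmc > 0 else float("nan")
    if not fmc_ratio > 0:
        raise ValueError("fully methylated control ratio must be positive")
    return (rmp_sample / actb_sample) / fmc_ratio * 100.0


def quantify_plate(
    plate: pd.DataFrame,
    target: str,
    actb: str = "ACTB",
    allow_qc_fail: bool = False,
) -> tuple[pd.DataFrame, dict[str, StandardCurve]]:
    """Full quantification of one plate for one methylation target.

    Fits standard curves for the target and the ACTB input assay from
    the plate's dilution series, converts sample mean Cq values to RMP,
    and normalizes against the fully methylated control (role ``fmc``).
    Returns (measurements, curves); measurements carry rmp, actb, nmp and
    log10(NMP+1) per sample, with samples lacking ACTB input flagged.
    """
    curves = {}
    for tgt in (target, actb):
        std = plate[(plate["target"] == tgt) & (plate["role"] == "standard")]
        agg = aggregate_cq(std)
        dil = std.groupby("sample")["dilution_pct"].first()
        curves[tgt] = fit_standard_curve(
            dil[agg["sample"]].to_numpy(), agg["cq"].to_numpy(), target=tgt
        )
    agg = aggregate_cq(plate)
    cq_of = {(r.target, r.sample): r.cq for r in agg.itertuples()}

    def rmp_of(tgt, sample):
        return estimate_rmp(cq_of.get((tgt, sample), float("nan")),
                            curves[tgt], allow_qc_fail=allow_qc_fail)

    rmp_fmc = rmp_of(target, "FMC")
    actb_fmc = rmp_of(actb, "FMC")
    rows = []
    samples = plate.loc[plate["role"] == "sample", "sample"].unique()
    for s in samples:
        rmp = rmp_of(target, s)
        inp = rmp_of(actb, s)
        try:
            nmp = normalize_nmp(rmp, inp, rmp_fmc, actb_fmc)
            valid = True
        except ValueError:
            nmp, valid = float("nan"), False
        rows.append({"sample_id": s, "target": target, "rmp": rmp, "actb": inp,
                     "nmp": nmp, "log_nmp": math.log10(nmp + 1) if nmp == nmp else float("nan"),
                     "valid": valid})
    return pd.DataFrame(rows), curves


def compare_groups(x, y, paired: bool = False) -> dict[str, float]:
    """Wilcoxon comparison of methylation levels between two groups.

    Unpaired: rank-sum (Mann-Whitney), exact when both sides have <= 25
    untied observations, normal approximation with continuity correction
    otherwise. Paired: signed-rank on matched vectors with zero
    differences dropped. Reports the two-sided p and the difference of
    group medians.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if len(x) != len(y):
            raise ValueError("paired comparison needs equal-length matched vectors")
        d = x - y
        d = d[d != 0]
        if d.size == 0:
            return {"p": 1.0, "median_diff": 0.0, "n": 0}
        mode = "exact" if d.size <= 25 else "approx"
        res = stats.wilcoxon(d, zero_method="wilcox", mode=mode)
        return {"p": float(res.pvalue), "median_diff": float(np.median(x - y)),
                "n": int(d.size)}
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= 25 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return {"p": float(res.pvalue),
            "median_diff": float(np.median(x) - np.median(y)),
            "n": int(len(x) + len(y))}
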