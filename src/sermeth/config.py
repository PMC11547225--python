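"""Configuration objects for simulation and the pipeline driver.

All knobs that matter scientifically live here with their defaults, so a
run is fully described by a (config, seed) pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

GROUPS: tuple[str, ...] = ("NCF", "LR-SL", "HR-HP", "HR-SP", "SAC")
"""Pathology groups, ordered by increasing severity: no colorectal
findings, low-risk serrated lesions, high-risk hyperplastic polyps,
high-risk serrated polyps, serrated adenocarcinoma."""

CGI_RELATIONS: tuple[str, ...] = ("CGI", "shore", "shelf", "opensea")
FEATURES: tuple[str, ...] = (
    "TSS200", "TSS1500", "5UTR", "1stExon", "Body", "3UTR", "intergenic"
)
PROMOTER_FEATURES: frozenset[str] = frozenset({"TSS200", "TSS1500", "5UTR", "1stExon"})


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic methylome cohort.

    The defaults emulate the study design this package targets: five
    pathology groups, serum cfDNA pooled 10 individuals per pool
    (sex-balanced), array-style probe annotation, a few hundred injected
    differentially methylated positions and a handful of clustered
    differential regions.

    Parameters
    ----------
    n_probes : total CpG probes on the synthetic array.
    n_individuals_per_group : individuals recruited per pathology group.
    pool_size : individuals pooled per array sample (must be even:
        half male, half female).
    n_dmp_true : isolated probes receiving a group-specific beta shift.
    n_dmr_true : clustered regions receiving a coherent shift.
    dmr_n_probes : (lo, hi) probes per injected region.
    dmr_span_gap_bp : (lo, hi) inter-probe gap inside injected regions;
        the upper bound must stay <= 250 bp so regions are clusterable.
    effect_size_beta : (lo, hi) magnitude of the injected |delta-beta|.
    affected_groups : groups whose mean beta is shifted at injected sites.
    batch_effect_sd : SD of the additive slide effect on the M scale.
    noise_kappa : precision of the Beta noise around group means for
        individual-level values (larger = less biological scatter).
    pool_noise_sd : SD (beta scale) of pool measurement noise.
    """

    n_probes: int = 20_000
    n_individuals_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"NCF": 30, "LR-SL": 30, "HR-HP": 20, "HR-SP": 20, "SAC": 10}
    )
    groups: Sequence[str] = GROUPS
    pool_size: int = 10
    n_dmp_true: int = 200
    n_dmr_true: int = 5
    dmr_n_probes: tuple[int, int] = (3, 6)
    dmr_span_gap_bp: tuple[int, int] = (20, 120)
    effect_size_beta: tuple[float, float] = (0.15, 0.25)
    affected_groups: Sequence[str] = ("HR-HP", "HR-SP", "SAC")
    batch_effect_sd: float = 0.2
    noise_kappa: float = 100.0
    pool_noise_sd: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.pool_size <= 0 or self.pool_size % 2 != 0:
            raise ConfigError("pool_size must be a positive even number (sex-balanced halves)")
        if self.n_probes <= 0:
            raise ConfigError("n_probes must be positive")
        lo, hi = self.effect_size_beta
        if not (0.0 <= lo <= hi < 1.0):
            raise ConfigError("effect_size_beta bounds must satisfy 0 <= lo <= hi < 1")
        if self.dmr_span_gap_bp[1] > 250:
            raise ConfigError("dmr_span_gap_bp upper bound must be <= 250 bp (clusterable)")
        if self.dmr_n_probes[0] < 2:
            raise ConfigError("injected regions need >= 2 probes")
        for g in self.affected_groups:
            if g not in self.groups:
                raise ConfigError(f"affected group {g!r} not in groups")
        for g, n in self.n_individuals_per_group.items():
            if n <= 0:
                raise ConfigError(f"group {g!r} has non-positive size")
        # crude capacity check: regions must fit among the probes
        if self.n_dmr_true * self.dmr_n_probes[1] + self.n_dmp_true > self.n_probes:
            raise ConfigError("requested injected sites exceed n_probes")


@dataclass
class QpcrSimConfig:
    """Parameters of the MS-qPCR plate simulator.

    Cq values follow the log-linear standard-curve model
    ``Cq = intercept + slope * log10(pct)``: ``slope`` is Cq per decade of
    % methylation (−3.3219 = perfect doubling each cycle) and ``intercept``
    is the Cq at the 1% reference point of the log scale.
    """

    slope: float = -3.3219
    intercept: float = 25.0
    cq_sd: float = 0.15
    dilution_points: tuple[float, ...] = (100.0, 10.0, 1.0, 0.1, 0.01)
    n_replicates: int = 3
    undetermined_cq_threshold: float = 40.0

    def validate(self) -> None:
        if self.slope >= 0:
            raise ConfigError("standard-curve slope must be negative")
        pts = self.dilution_points
        if any(p <= 0 for p in pts) or any(a >= b for a, b in zip(pts[1:], pts)):
            raise ConfigError("dilution points must be strictly decreasing and positive")
        if self.n_replicates < 1:
            raise ConfigError("need >= 1 replicate")


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings (thresholds follow the study design)."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    qpcr: QpcrSimConfig = field(default_factory=QpcrSimConfig)
    contrasts: Sequence[tuple[str, str]] = (
        ("HR-SP", "NCF"), ("HR-HP", "NCF"), ("SAC", "NCF"),
        ("HR-SP", "LR-SL"), ("HR-HP", "LR-SL"), ("HR-SP", "HR-HP"),
    )
    p_thresh: float = 0.01
    db_thresh: float = 0.10
    maxgap: int = 250
    n_permutations: int = 100
    fwer_thresh: float = 0.10
    cutoff_quantile: float = 0.99
    alpha_assumptions: float = 0.01
    clip_eps: float = 1e-6
    detection_fail_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        self.sim.validate()
        self.qpcr.validate()
        for thr, name in [(self.p_thresh, "p_thresh"), (self.db_thresh, "db_thresh"),
                          (self.fwer_thresh, "fwer_thresh"),
                          (self.cutoff_quantile, "cutoff_quantile"),
                          (self.alpha_assumptions, "alpha_assumptions")]:
            if not 0 < thr < 1:
                raise ConfigError(f"{name} must lie in (0,1)")
        if self.maxgap <= 0 or self.n_permutations < 1:
            raise ConfigError("maxgap and n_permutations must be positive")

    def to_dict(self) -> dict:
        return asdict(self)
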