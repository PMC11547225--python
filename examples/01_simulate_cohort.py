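"""Simulate a pooled serum cfDNA methylation cohort.

Builds a five-group cohort (controls through serrated adenocarcinoma),
pools individuals ten at a time with equal DNA mass, and prints the
design. The truth object records which probes and regions carry real
group differences, which is what every downstream recovery test uses.
"""

import numpy as np

from sermeth import synthdata
from sermeth.config import SimulationConfig

cfg = SimulationConfig(n_probes=5000, seed=42)
beta, ann, sheet, truth = synthdata.simulate_individuals(cfg)
pooled, pool_sheet = synthdata.pool_samples(
    beta, sheet, cfg.pool_size, batch_effect_sd=cfg.batch_effect_sd,
    noise_sd=cfg.pool_noise_sd, rng=np.random.default_rng(43),
)

print(f"individuals: {beta.shape[1]}, probes: {beta.shape[0]}")
print(f"pools ({pooled.shape[1]} arrays):")
print(pool_sheet[["group", "batch"]].to_string())
print(f"\ninjected truth: {len(truth.true_dmp_ids)} differential positions, "
      f"{len(truth.true_dmr_intervals)} differential regions")
print(truth.true_dmr_intervals[["chrom", "start", "end", "direction",
                                "n_probes"]].to_string(index=False))
# Each pool averages ten sex-balanced individuals from one pathology
# group; the slide column is the array batch that ComBat later removes.
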