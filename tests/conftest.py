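import numpy as np
import pandas as pd
import pytest

from sermeth import preprocess, synthdata
from sermeth.config import SimulationConfig


def two_group_config(**kw) -> SimulationConfig:
    """A compact two-group cohort (NCF controls vs HR-SP cases)."""
    defaults = dict(
        n_probes=2000,
        n_individuals_per_group={"NCF": 30, "HR-SP": 30},
        groups=("NCF", "HR-SP"),
        affected_groups=("HR-SP",),
        n_dmp_true=20,
        n_dmr_true=2,
        batch_effect_sd=0.0,
        seed=1,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    """Simulated two-group cohort pooled into 3 + 3 arrays."""
    cfg = two_group_config()
    beta, ann, sheet, truth = synthdata.simulate_individuals(cfg)
    rng = np.random.default_rng(99)
    pooled, pool_sheet = synthdata.pool_samples(beta, sheet, cfg.pool_size,
                                                noise_sd=0.01, rng=rng)
    m = preprocess.beta_to_m(pooled)
    groups = pool_sheet["group"]
    return {
        "config": cfg, "beta_ind": beta, "ann": ann, "sheet": sheet,
        "truth": truth, "pooled": pooled, "pool_sheet": pool_sheet, "m": m,
        "case": list(groups.index[groups == "HR-SP"]),
        "control": list(groups.index[groups == "NCF"]),
    }


@pytest.fixture()
def toy_annotation():
    return pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1", "chr2", "chr2", "chrX"],
            "pos": [100, 200, 600, 100, 350, 50],
            "cgi_relation": ["CGI", "CGI", "shore", "opensea", "opensea", "CGI"],
            "feature": ["TSS200", "TSS200", "Body", "intergenic", "Body", "TSS1500"],
            "genes": ["GA", "GA;GB", "GB", "", "GC", "GX"],
            "cross_reactive": [False, False, True, False, False, False],
            "snp": [False] * 6,
            "sex_chrom": [False, False, False, False, False, True],
        },
        index=pd.Index([f"cg{i}" for i in range(6)], name="probe_id"),
    )
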