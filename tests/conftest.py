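import numpy as np
import pandas as pd
import pytest

from siccaomics.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def qtl_cohort():
    """400+400 cohort with planted cis and case-only meQTLs, DEGs."""
    cfg = SimulationConfig(
        n_cases=400, n_controls=400, n_cpgs=1000, n_genes=300, n_snps=200,
        n_meqtl=50, qtl_effect_range=(0.05, 0.05), n_int_meqtl=50,
        n_deg=50, log2fc_range=(2.0, 2.0), seed=21,
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def chain_cohort():
    """Cohort with the HLA → SSA → IFN-hypomethylation-block causal chain."""
    cfg = SimulationConfig(
        n_cases=400, n_controls=400, n_cpgs=100, n_genes=10, n_snps=10,
        ifn_block_size=10, seed=7,
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture()
def tiny_sheet():
    """Minimal 6-sample sheet for hand-built scans."""
    from siccaomics.io import SampleSheet

    return SampleSheet(pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(6)],
        "disease": ["case"] * 3 + ["control"] * 3,
        "sex": ["F", "M", "F", "F", "M", "F"],
        "age": [50.0, 60, 55, 48, 62, 51],
    }))
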