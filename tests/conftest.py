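import numpy as np
import pytest

from poolsweep import synthetic_data as synth


@pytest.fixture(scope="session")
def sweep_sim():
    """700 kb, 3 pools, 20-window complete sweep core + 10-window extension."""
    cfg = synth.SimConfig(
        genome_length=700_000,
        theta=0.02,
        error_rate=0.0,
        seed=7,
        sweep_core=(300_001, 400_000),
        sweep_extension=(400_001, 450_000, 2),
        diversity_reduction=0.0,
        fixed_snp_pos=350_001,
        outlier_snps=[
            (120_001, (0.95, 0.95, 0.05)),
            (480_001, (0.05, 0.05, 0.95)),
        ],
    )
    return cfg, synth.simulate_counts(cfg)


@pytest.fixture(scope="session")
def small_sim():
    """50 kb quick fixture with a fixed nonsynonymous SNP and one outlier."""
    cfg = synth.SimConfig(
        genome_length=50_000,
        theta=0.02,
        error_rate=0.001,
        seed=3,
        fixed_snp_pos=25_002,
        outlier_snps=[(40_001, (0.9, 0.1, 0.1))],
    )
    return cfg, synth.simulate_counts(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
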