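import numpy as np
import pytest

from dmrscan import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def null_sim():
    """13v13, 2,000 windows, phi=0.1, depth 30, no planted signal."""
    cfg = SimConfig(
        n_chromosomes=2, chrom_length=1_000_000, n_planted_dmrs=0,
        dispersion=0.1, base_mean_depth=30.0, seed=5,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def planted_sim():
    """13v13, 2,000 windows, 50 planted fold-2.5 DMRs, phi=0.1, depth 30."""
    cfg = SimConfig(
        n_chromosomes=2, chrom_length=1_000_000, n_planted_dmrs=50,
        effect_fold=2.5, dispersion=0.1, base_mean_depth=30.0, seed=7,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_sim():
    """4v4, 400 windows, strong signal — cheap classifier checks."""
    cfg = SimConfig(
        n_chromosomes=1, chrom_length=400_000, n_planted_dmrs=15,
        effect_fold=3.0, n_case=4, n_control=4, base_mean_depth=50.0, seed=33,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
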