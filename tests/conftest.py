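import numpy as np
import pytest

from epistate.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def small_dataset():
    """Small noiseless synthetic study shared across tests (seed-fixed)."""
    cfg = SimulationConfig(n_chroms=2, chrom_length=1_000_000, n_genes=200)
    return simulate_all(cfg, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
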