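import numpy as np
import pytest

from kineticnet.simulate import SimConfig, simulate_truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study conditions for fast unit tests."""
    # median-of-ratios normalization needs dynamic peaks to stay a small
    # minority (the emulated data had ~13% dynamic), so n_res cannot shrink
    # proportionally with the planted program
    return SimConfig(n_res=400, n_genes=110, n_permutations=120, seed=7)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_truth(small_config)


@pytest.fixture(scope="session")
def default_truth():
    """One default-scale truth set shared across tests."""
    return simulate_truth(SimConfig(seed=11))
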