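import numpy as np
import pytest

from glycoscreen import SimulationConfig, simulate_screen


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_zero_noise_screen():
    """A 120-gene zero-noise screen shared by pipeline-level tests."""
    cfg = SimulationConfig(n_genes=120).zero_noise()
    return simulate_screen(cfg, seed=11)


@pytest.fixture(scope="session")
def small_noisy_screen():
    cfg = SimulationConfig(n_genes=120)
    return simulate_screen(cfg, seed=11, label_truth=False)
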