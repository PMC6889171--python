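import numpy as np
import pytest

from tslrf.simulate import SimulationConfig, simulate_dataset, simulate_genotypes


@pytest.fixture(scope="session")
def small_truth():
    """A small signal-bearing dataset: 80 samples, 300 markers, 6 QTNs."""
    return simulate_dataset(SimulationConfig(n=80, p=300), seed=1234)


@pytest.fixture(scope="session")
def random_genotypes_20x50():
    return simulate_genotypes(20, 50, 0.30, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
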