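import numpy as np
import pytest

from wcsgnet.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The standard 3-type, 600-cell, 200-gene simulated dataset."""
    return simulate_dataset(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def small_dataset():
    """A small dataset for fast end-to-end paths."""
    cfg = SimulationConfig(
        n_types=3,
        cells_per_type=[60, 60, 60],
        n_genes=60,
        module_size=8,
        correlation=0.8,
        seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
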