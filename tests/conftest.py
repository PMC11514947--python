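import numpy as np
import pytest

from histodomain import SimulationSpec, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default 20x20 / K=3 synthetic fixture (seed 1)."""
    return simulate_dataset(SimulationSpec(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """A fast 8x8 fixture for pipeline-level tests."""
    spec = SimulationSpec(n_rows=8, n_cols=8, n_null_genes=30, n_deg_genes=10,
                          seed=11)
    return simulate_dataset(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
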