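import numpy as np
import pytest
from hypothesis import settings

from avalanches import BranchingConfig, simulate_branching_avalanches

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def critical_catalog():
    """Medium-sized critical (m=1) branching catalog shared across tests."""
    truth = simulate_branching_avalanches(
        BranchingConfig(m=1.0, n_avalanches=40_000, seed=20240901)
    )
    return truth.catalog


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_raster_arrays(rng, n_neurons=8, n_spikes=60, t_max=200):
    """Random frame-locked raster arrays for extraction fixtures."""
    ids = rng.integers(0, n_neurons, n_spikes)
    times = rng.integers(0, t_max, n_spikes).astype(float)
    return ids, times, n_neurons
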