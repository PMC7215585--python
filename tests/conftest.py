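import numpy as np
import pytest

from meareplay import ElectrodeGrid, SpikeData, make_default_network


@pytest.fixture
def small_grid():
    """A 4x4 grid (corners inactive -> 12 electrodes) for fast toy tests."""
    return ElectrodeGrid(shape=(4, 4), pitch_um=200.0)


@pytest.fixture
def toy_spikes(small_grid):
    """Hand-placed spikes on three electrodes of the small grid."""
    spikes = {
        1: np.array([5.2, 30.0, 31.0, 950.0]),
        5: np.array([100.0, 200.0, 300.0]),
        6: np.array([]),
    }
    return SpikeData(spikes, duration_ms=1000.0, geometry=small_grid)


@pytest.fixture
def default_net():
    return make_default_network(seed=42)
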