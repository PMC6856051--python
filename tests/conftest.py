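import numpy as np
import pytest

from ionliquid.dynamics import DynamicsConfig
from ionliquid.grid import BinMapping
from ionliquid.topology import TopologyConfig, generate_random_topology


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_topology():
    """A 4x4-neuron liquid in a 16x16 grid with the default length ranges."""
    cfg = TopologyConfig(grid_width=16, grid_height=16, lattice=4)
    return generate_random_topology(cfg, seed=7)


@pytest.fixture
def small_dynamics():
    return DynamicsConfig(k=1)


@pytest.fixture
def two_channel_mapping():
    """Two input bins in opposite halves of a 16x16 grid, strong drive."""
    return BinMapping(
        targets=np.array([[3, 8], [12, 8]]),
        grid_width=16,
        grid_height=16,
        gain=20.0,
    )
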