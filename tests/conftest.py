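import numpy as np
import pytest

from ierp.adjacency import build_lattice_adjacency
from ierp.modes import make_mode_labels
from ierp.spectral import ModeRange


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def standard_lattice():
    """The 15-mode lattice (orders 2..6+) used throughout the worked
    examples, with its labels."""
    mr = ModeRange(p_min=2, trend_start=6)
    return mr, make_mode_labels(mr)


@pytest.fixture(scope="session")
def mode_time_graph(standard_lattice):
    """2-D [mode, time] graph: 15 modes x 50 bins."""
    _, labels = standard_lattice
    return build_lattice_adjacency(labels, n_time=50, dims=("mode", "time"))
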