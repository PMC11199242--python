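import numpy as np
import pytest

from mstate import synth
from mstate.core import NeighborGraph, Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sphere32():
    return synth.sensor_sphere(32)


@pytest.fixture(scope="session")
def states4():
    """Four planted template maps on 32 synthetic channels."""
    return synth.make_template_maps(32, 4, seed=1)


@pytest.fixture(scope="session")
def resting_rec(states4):
    rec, gt = synth.simulate_resting(
        states4, duration_s=40.0, snr=10.0, seed=7, coverages=[0.4, 0.3, 0.2, 0.1]
    )
    return rec, gt


@pytest.fixture(scope="session")
def gonogo_data(states4):
    epochs, rt, gt = synth.simulate_gonogo(
        states4, n_go=60, n_nogo=40, ern_amplitude_uv=-5.0, snr=10.0, seed=11
    )
    return epochs, rt, gt


@pytest.fixture
def chain_graph():
    """1-D chain of 8 channels; interior nodes have symmetric neighbors."""
    n = 8
    nb = np.zeros((n, 2), dtype=int)
    for i in range(n):
        left = i - 1 if i > 0 else i + 2
        right = i + 1 if i < n - 1 else i - 2
        nb[i] = (left, right)
    return NeighborGraph(neighbors=nb, k_neighbors=2)


@pytest.fixture
def star_graph():
    """7 channels where everyone neighbors everyone else (complete graph)."""
    n = 7
    nb = np.array([[j for j in range(n) if j != i] for i in range(n)])
    return NeighborGraph(neighbors=nb, k_neighbors=6)


def recording_from_gfp(series):
    """Two-channel recording whose GFP trace equals |series|."""
    series = np.asarray(series, dtype=float)
    data = np.vstack([series, -series])
    return Recording(data=data, sr=250.0)
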