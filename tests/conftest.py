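import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from effconn import EffectiveNetwork, SpikeRaster, complete_network


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_network(adjacency, weights=None):
    adjacency = np.asarray(adjacency)
    if weights is None:
        weights = adjacency.astype(float)
    return EffectiveNetwork(adjacency, np.asarray(weights, dtype=float))


def cycle_network(n=3, weight=1.0):
    """Directed n-cycle 0 -> 1 -> ... -> n-1 -> 0."""
    a = np.zeros((n, n), dtype=int)
    for i in range(n):
        a[i, (i + 1) % n] = 1
    return make_network(a, weight * a)


def random_network(n, density, rng, weighted=False):
    a = (rng.random((n, n)) < density).astype(int)
    np.fill_diagonal(a, 0)
    w = a * rng.uniform(0.1, 0.9, size=(n, n)) if weighted else a.astype(float)
    return make_network(a, w)


@pytest.fixture
def complete5():
    return complete_network(5)


def raster_from_rows(rows, frame_rate=27.33):
    return SpikeRaster(np.asarray(rows, dtype=int), frame_rate=frame_rate)
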