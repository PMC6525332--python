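import numpy as np
import pandas as pd
import pytest

from zfnet.datasets import COORD_COLUMNS, TraceDataset
from zfnet.network import BinaryNetwork, CorrelationNetwork


def make_dataset(traces, frame_interval=1.0, **meta):
    traces = np.asarray(traces, dtype=float)
    n = traces.shape[0]
    rng = np.random.default_rng(0)
    coords = pd.DataFrame({
        "roi_id": np.arange(n),
        "x_um": rng.uniform(0, 100, n),
        "y_um": rng.uniform(0, 100, n),
        "plane": np.zeros(n, dtype=int),
        "z_um": np.zeros(n),
    }, columns=COORD_COLUMNS)
    return TraceDataset(traces=traces, coords=coords,
                        frame_interval=frame_interval, meta=meta)


def net_from_weights(weights):
    w = np.asarray(weights, dtype=float)
    np.fill_diagonal(w, 0.0)
    return CorrelationNetwork(weights=w, node_ids=np.arange(w.shape[0]))


def bnet_from_edges(n, edges):
    a = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return BinaryNetwork(adjacency=a, threshold=np.nan)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def k4_minus_edge():
    return bnet_from_edges(4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)])


@pytest.fixture
def star4():
    return bnet_from_edges(4, [(0, 1), (0, 2), (0, 3)])


@pytest.fixture
def complete4():
    return bnet_from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])


@pytest.fixture
def cycle5():
    return bnet_from_edges(5, [(i, (i + 1) % 5) for i in range(5)])
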