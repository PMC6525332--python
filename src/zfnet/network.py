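"""Weighted correlation networks, edge-weight distributions, binarization.

Nodes are ROIs; the edge weight between nodes i and j is the sample
Pearson correlation of their ΔF/F traces.  Binary networks keep an edge
wherever the weight strictly exceeds a global threshold τ; all graph
metrics downstream operate on these binary, undirected, self-loop-free
adjacency matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import TraceDataset


class NetworkError(ValueError):
    pass


@dataclass
class CorrelationNetwork:
    """Symmetric matrix of pairwise Pearson coefficients, zero diagonal."""

    weights: np.ndarray
    node_ids: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.node_ids = np.asarray(self.node_ids)
        n = self.weights.shape[0]
        if self.weights.shape != (n, n):
            raise NetworkError("weights must be square")
        if self.node_ids.shape[0] != n:
            raise NetworkError("node_ids length must match weights")

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.n * (self.n - 1) // 2

    def upper_weights(self) -> np.ndarray:
        """The n(n−1)/2 distinct pairwise weights (upper triangle)."""
        iu = np.triu_indices(self.n, k=1)
        return self.weights[iu]


@dataclass
class BinaryNetwork:
    """Thresholded, binarized, undirected adjacency structure."""

    adjacency: np.ndarray
    threshold: float
    source_density: float = np.nan

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)
        if self.adjacency.dtype != np.int8:
            self.adjacency = self.adjacency.astype(np.int8)

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class EdgeWeightDistribution:
    """Cumulative edge-weight distribution: 50 bins on [−1, 1].

    ``cumulative[k]`` is the fraction of pairwise weights ≤ the right edge
    of bin k; the final value is 1 (every Pearson coefficient is ≤ 1).
    """

    bin_edges: np.ndarray
    cumulative: np.ndarray
    n_pairs: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_right_edge": self.bin_edges[1:], "cumulative": self.cumulative}
        )


@dataclass
class MetricCurve:
    """One metric evaluated over the threshold grid for one network."""

    grid: np.ndarray
    values: np.ndarray
    metric: str
    larva_id: str = ""
    extra: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"larva_id": self.larva_id, "tau": self.grid,
             "metric": self.metric, "value": self.values}
        )


def correlation_matrix(dataset: TraceDataset) -> CorrelationNetwork:
    """Pairwise Pearson correlation of ΔF/F traces; diagonal set to 0.

    The dataset must be cleaned first: a zero-variance trace makes the
    coefficient undefined and raises.
    """
    if dataset.n_rois < 2:
        raise NetworkError("correlation_matrix needs at least 2 ROIs")
    sd = dataset.traces.std(axis=1)
    if not np.isfinite(dataset.traces).all() or np.any(sd == 0):
        raise NetworkError(
            "zero-variance or non-finite trace encountered; run clean_traces first"
        )
    w = np.corrcoef(dataset.traces)
    w = 0.5 * (w + w.T)  # BLAS products are not bitwise symmetric
    np.clip(w, -1.0, 1.0, out=w)  # guard rounding just past ±1
    np.fill_diagonal(w, 0.0)
    return CorrelationNetwork(weights=w, node_ids=dataset.coords["roi_id"].to_numpy())


def edge_weight_cdf(net: CorrelationNetwork, n_bins: int = 50) -> EdgeWeightDistribution:
    """Cumulative probability distribution of the pairwise weights.

    Uses ``n_bins`` equal-width bins spanning [−1, 1]; bin membership is
    right-edge inclusive so the last entry is exactly 1.
    """
    if net.n < 2:
        raise NetworkError("edge_weight_cdf needs at least 2 nodes")
    w = net.upper_weights()
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    cumulative = np.array([(w <= e).mean() for e in edges[1:]])
    return EdgeWeightDistribution(bin_edges=edges, cumulative=cumulative, n_pairs=w.size)


def threshold_binarize(net: CorrelationNetwork, tau: float) -> BinaryNetwork:
    """Keep edges with weight strictly greater than τ; binarize.

    Mirrors absolute thresholding followed by binary weight conversion.
    Strict inequality means exactly-zero correlations are dropped at τ = 0
    and negative weights never survive τ ≥ 0.
    """
    if not -1.0 <= tau <= 1.0:
        raise NetworkError("tau must be in [-1, 1]")
    adj = (net.weights > tau)
    np.fill_diagonal(adj, False)
    bnet = BinaryNetwork(adjacency=adj.astype(np.int8), threshold=tau)
    bnet.source_density = network_density(bnet)
    return bnet


def network_density(bnet: BinaryNetwork) -> float:
    """Fraction of realized edges among all n(n−1)/2 possible pairs."""
    n = bnet.n
    if n < 2:
        raise NetworkError("density needs at least 2 nodes")
    return bnet.n_edges / (n * (n - 1) / 2)


def density_curve(net: CorrelationNetwork, tau_grid) -> MetricCurve:
    """Network density at each threshold of a sorted grid (non-increasing)."""
    tau_grid = np.asarray(tau_grid, dtype=float)
    if np.any(np.diff(tau_grid) < 0):
        raise NetworkError("tau_grid must be sorted ascending")
    w = net.upper_weights()
    values = np.array([(w > t).mean() for t in tau_grid])
    return MetricCurve(grid=tau_grid, values=values, metric="density")


DEFAULT_TAU_GRID = np.round(np.arange(0.0, 0.7001, 0.1), 10)
DEFAULT_DENSITY_GRID = np.round(np.arange(0.0, 0.9001, 0.1), 10)
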