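"""Binary undirected graph measures: degree, clustering, path length,
transitivity, degree assortativity.

All measures follow the standard binary-undirected definitions:

* per-node clustering  c_i = 2 t_i / (k_i (k_i − 1)), with t_i the number
  of closed triangles around node i; nodes with k_i < 2 contribute c_i = 0;
  the network value Cl is the mean over all nodes
* characteristic path length  L = mean shortest-path distance over ordered
  node pairs with a finite distance (unreachable pairs are counted and
  reported, not averaged)
* transitivity  T = Σ 2 t_i / Σ k_i (k_i − 1)
* assortativity  r = Pearson correlation of end-node degrees over edges

Undefined values (no edges, zero degree variance, no reachable pairs)
propagate as NaN and are never silently coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .network import BinaryNetwork


@dataclass
class GraphSummary:
    """Scalar measures of one binary network."""

    n: int
    n_edges: int
    density: float
    cl: float           # mean clustering coefficient
    l: float            # characteristic path length (NaN if no finite pair)
    t: float            # transitivity (NaN if no connected triple)
    r: float            # degree assortativity (NaN if degenerate)
    n_unreachable_pairs: int

    def as_dict(self) -> dict:
        return {
            "n": self.n, "n_edges": self.n_edges, "density": self.density,
            "cl": self.cl, "l": self.l, "t": self.t, "r": self.r,
            "n_unreachable_pairs": self.n_unreachable_pairs,
        }


def degrees(bnet: BinaryNetwork) -> np.ndarray:
    """Per-node degree k_i (row sums of the adjacency matrix)."""
    return bnet.adjacency.sum(axis=1).astype(np.int64)


def triangle_counts(bnet: BinaryNetwork) -> np.ndarray:
    """Closed triangles around each node: t_i = (A³)_ii / 2."""
    a = bnet.adjacency.astype(np.float64)
    return np.round(np.einsum("ij,jk,ki->i", a, a, a) / 2.0).astype(np.int64)


def clustering(bnet: BinaryNetwork) -> tuple[np.ndarray, float]:
    """Per-node clustering coefficients and their mean Cl."""
    k = degrees(bnet)
    t = triangle_counts(bnet)
    c = np.zeros(bnet.n)
    mask = k >= 2
    c[mask] = 2.0 * t[mask] / (k[mask] * (k[mask] - 1.0))
    return c, float(c.mean()) if bnet.n else np.nan


def characteristic_path_length(bnet: BinaryNetwork) -> tuple[float, int]:
    """Mean shortest path over reachable ordered pairs, plus the number of
    unreachable ordered pairs.

    High thresholds routinely disconnect these networks, so unreachable
    pairs are excluded from the mean (their count is returned for
    diagnostics).  Returns (NaN, all pairs) for an edgeless network.
    """
    n = bnet.n
    if n < 2:
        raise ValueError("characteristic_path_length needs at least 2 nodes")
    d = shortest_path(csr_matrix(bnet.adjacency), method="D", unweighted=True)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    n_unreachable = int(off.sum() - finite.sum())
    if not finite.any():
        return np.nan, n_unreachable
    return float(d[finite].mean()), n_unreachable


def transitivity(bnet: BinaryNetwork) -> float:
    """Global triangle ratio T = Σ 2 t_i / Σ k_i (k_i − 1); NaN if no node
    has degree ≥ 2."""
    k = degrees(bnet)
    denom = float((k * (k - 1)).sum())
    if denom == 0:
        return np.nan
    return float(2.0 * triangle_counts(bnet).sum() / denom)


def assortativity(bnet: BinaryNetwork) -> float:
    """Degree assortativity: the correlation coefficient of the degrees at
    the two ends of each edge.

    Evaluated over the edge list with each undirected edge counted once,
    degrees entering symmetrically.  NaN when the degree variance over
    edges is zero (e.g. regular graphs); raises on an edgeless network.
    """
    if bnet.n_edges == 0:
        raise ValueError("assortativity requires at least one edge")
    i, j = np.triu_indices(bnet.n, k=1)
    present = bnet.adjacency[i, j] > 0
    ki = degrees(bnet)[i[present]].astype(float)
    kj = degrees(bnet)[j[present]].astype(float)
    linv = 1.0 / ki.size
    num = linv * (ki * kj).sum() - (linv * (0.5 * (ki + kj)).sum()) ** 2
    den = linv * (0.5 * (ki**2 + kj**2)).sum() - (linv * (0.5 * (ki + kj)).sum()) ** 2
    if den == 0:
        return np.nan
    return float(num / den)


def graph_summary(bnet: BinaryNetwork) -> GraphSummary:
    """All scalar measures of one binary network in one pass."""
    _, cl = clustering(bnet)
    l, n_unreach = characteristic_path_length(bnet)
    t = transitivity(bnet)
    r = assortativity(bnet) if bnet.n_edges > 0 else np.nan
    n = bnet.n
    return GraphSummary(
        n=n,
        n_edges=bnet.n_edges,
        density=bnet.n_edges / (n * (n - 1) / 2) if n >= 2 else np.nan,
        cl=cl, l=l, t=t, r=r,
        n_unreachable_pairs=n_unreach,
    )
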