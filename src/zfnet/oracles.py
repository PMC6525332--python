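"""Brute-force reference implementations used to validate the fast paths.

These are deliberately naive — explicit triple loops over node triples,
Floyd–Warshall over the full distance matrix, direct edge-list formula
evaluation, per-window scans — so they share no code with
:mod:`zfnet.metrics` or :mod:`zfnet.spatial` and can serve as independent
oracles in validation and tests.  They are only practical for small
graphs (n ≲ 50).
"""

from __future__ import annotations

import numpy as np


def brute_clustering(adj: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node clustering and mean by enumerating all node triples."""
    a = np.asarray(adj)
    n = a.shape[0]
    c = np.zeros(n)
    for i in range(n):
        k = int(a[i].sum())
        if k < 2:
            continue
        t = 0
        for j in range(n):
            for h in range(j + 1, n):
                if a[i, j] and a[i, h] and a[j, h]:
                    t += 1
        c[i] = 2.0 * t / (k * (k - 1))
    return c, float(c.mean()) if n else np.nan


def brute_path_length(adj: np.ndarray) -> tuple[float, int]:
    """Characteristic path length via Floyd–Warshall; returns (L, number
    of unreachable ordered pairs)."""
    a = np.asarray(adj)
    n = a.shape[0]
    inf = float("inf")
    d = [[0.0 if i == j else (1.0 if a[i][j] else inf) for j in range(n)]
         for i in range(n)]
    for m in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][m] + d[m][j] < d[i][j]:
                    d[i][j] = d[i][m] + d[m][j]
    finite, total, unreachable = [], 0, 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            total += 1
            if d[i][j] == inf:
                unreachable += 1
            else:
                finite.append(d[i][j])
    if not finite:
        return np.nan, unreachable
    return float(sum(finite) / len(finite)), unreachable


def brute_transitivity(adj: np.ndarray) -> float:
    """Triangle ratio by enumerating all triples; NaN if no connected triple."""
    a = np.asarray(adj)
    n = a.shape[0]
    triangles = 0
    for i in range(n):
        for j in range(i + 1, n):
            for h in range(j + 1, n):
                if a[i, j] and a[i, h] and a[j, h]:
                    triangles += 1
    denom = sum(int(a[i].sum()) * (int(a[i].sum()) - 1) for i in range(n))
    if denom == 0:
        return np.nan
    return 6.0 * triangles / denom  # each triangle closes 2 triples at 3 nodes


def brute_assortativity(adj: np.ndarray) -> float:
    """Degree assortativity by direct evaluation of the edge-list formula."""
    a = np.asarray(adj)
    n = a.shape[0]
    deg = [int(a[i].sum()) for i in range(n)]
    edges = [(i, j) for i in range(n) for j in range(i + 1, n) if a[i, j]]
    if not edges:
        raise ValueError("no edges")
    l = len(edges)
    s_prod = sum(deg[i] * deg[j] for i, j in edges) / l
    s_mean = sum(0.5 * (deg[i] + deg[j]) for i, j in edges) / l
    s_sq = sum(0.5 * (deg[i] ** 2 + deg[j] ** 2) for i, j in edges) / l
    den = s_sq - s_mean**2
    if den == 0:
        return np.nan
    return (s_prod - s_mean**2) / den


def brute_window_mean(
    xy: np.ndarray, values: np.ndarray, origin: tuple[float, float], window: float
) -> tuple[float, int]:
    """Mean metric over ROIs inside one window (lower edge inclusive)."""
    ox, oy = origin
    acc, count = 0.0, 0
    for (x, y), v in zip(xy, values):
        if ox <= x < ox + window and oy <= y < oy + window:
            acc += v
            count += 1
    return (acc / count if count else np.nan), count


def brute_ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample KS D as the sup of |ECDF_a − ECDF_b| by direct counting."""
    a = np.sort(np.asarray(a, float))
    b = np.sort(np.asarray(b, float))
    grid = np.concatenate([a, b])
    d = 0.0
    for v in grid:
        fa = np.searchsorted(a, v, side="right") / a.size
        fb = np.searchsorted(b, v, side="right") / b.size
        d = max(d, abs(fa - fb))
    return d
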