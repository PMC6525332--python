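"""Group aggregation and the three statistical comparisons.

Per-larva metric curves are averaged within a group (mean ± SEM at each
threshold or bin).  Groups are compared by:

* unpaired two-tailed Student's t test per threshold (normally
  distributed graph metrics; no correction across thresholds by default,
  the number of tests performed is always recorded)
* one-way ANOVA with Tukey HSD across developmental ages
* two-sample Kolmogorov–Smirnov on pooled pairwise correlation
  coefficients (pooling all upper-triangle weights across the larvae of a
  group — the convention that yields per-group n in the millions for real
  multiplane datasets)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .datasets import TraceDataset
from .network import CorrelationNetwork, MetricCurve, correlation_matrix


class StatsError(ValueError):
    pass


@dataclass
class GroupSummary:
    """Pointwise mean ± SEM of a metric across the larvae of one group."""

    key: tuple
    grid: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray          # larvae contributing per grid point
    metric: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "group": [str(self.key)] * self.grid.size,
            "grid": self.grid, "metric": self.metric,
            "mean": self.mean, "sem": self.sem, "n": self.n,
        })


@dataclass
class ComparisonResult:
    """Tidy result of one statistical comparison.

    ``table`` has one row per threshold (or a single pooled row) with the
    statistic, p-value, group sizes and significance flag at ``alpha``.
    """

    test: str
    table: pd.DataFrame
    alpha: float = 0.05
    n_tests: int = 1
    extra: dict = field(default_factory=dict)


def _curve_values(curve) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(curve, MetricCurve):
        return np.asarray(curve.grid, float), np.asarray(curve.values, float)
    # EdgeWeightDistribution
    return np.asarray(curve.bin_edges[1:], float), np.asarray(curve.cumulative, float)


def group_average(curves: Sequence, key: tuple = (), metric: str = "") -> GroupSummary:
    """Pointwise mean and SEM across larvae; all curves must share the grid.

    Missing (NaN) cells are excluded, with the contributing count reported
    per cell; SEM is the sample standard deviation over larvae divided by
    √n and is NaN where fewer than 2 larvae contribute.
    """
    if not curves:
        raise StatsError("group_average needs at least one curve")
    grid0, v0 = _curve_values(curves[0])
    values = [v0]
    for c in curves[1:]:
        g, v = _curve_values(c)
        if g.shape != grid0.shape or not np.allclose(g, grid0):
            raise StatsError("curves have mismatched grids")
        values.append(v)
    mat = np.vstack(values)
    defined = np.isfinite(mat)
    n = defined.sum(axis=0)
    filled = np.where(defined, mat, 0.0)
    mean = np.where(n >= 1, filled.sum(axis=0) / np.maximum(n, 1), np.nan)
    dev2 = np.where(defined, (mat - np.where(n >= 1, mean, 0.0)[None, :]) ** 2, 0.0)
    sd = np.where(n >= 2, np.sqrt(dev2.sum(axis=0) / np.maximum(n - 1, 1)), np.nan)
    sem = sd / np.sqrt(np.maximum(n, 1))
    if not metric and isinstance(curves[0], MetricCurve):
        metric = curves[0].metric
    return GroupSummary(key=key, grid=grid0, mean=mean, sem=sem, n=n, metric=metric)


def per_threshold_ttest(
    group_a: Sequence[MetricCurve],
    group_b: Sequence[MetricCurve],
    equal_var: bool = True,
    alpha: float = 0.05,
    correction: str | None = None,
) -> ComparisonResult:
    """Unpaired two-tailed t test at each threshold of a shared grid.

    Student's (pooled-variance) form by default; ``equal_var=False``
    selects Welch.  No correction across thresholds unless
    ``correction="bonferroni"``; the number of tests is recorded either
    way.  Cells with fewer than 2 larvae in either group are flagged
    missing.
    """
    if not group_a or not group_b:
        raise StatsError("both groups need at least one curve")
    grid, _ = _curve_values(group_a[0])
    a = np.vstack([_curve_values(c)[1] for c in group_a])
    b = np.vstack([_curve_values(c)[1] for c in group_b])
    rows = []
    for k, tau in enumerate(grid):
        xa = a[:, k][np.isfinite(a[:, k])]
        xb = b[:, k][np.isfinite(b[:, k])]
        if xa.size < 2 or xb.size < 2:
            rows.append({"tau": tau, "statistic": np.nan, "p": np.nan,
                         "n_a": xa.size, "n_b": xb.size, "flag": "insufficient_n"})
            continue
        flag = ""
        if xa.std(ddof=1) == 0 and xb.std(ddof=1) == 0:
            flag = "degenerate_zero_variance"
        res = sps.ttest_ind(xa, xb, equal_var=equal_var)
        rows.append({"tau": tau, "statistic": float(res.statistic),
                     "p": float(res.pvalue), "n_a": xa.size, "n_b": xb.size,
                     "flag": flag})
    table = pd.DataFrame(rows)
    n_tests = int(np.isfinite(table["p"]).sum())
    if correction == "bonferroni":
        finite = np.isfinite(table["p"])
        adj = np.full(len(table), np.nan)
        if finite.any():
            adj[finite.to_numpy()] = multipletests(
                table.loc[finite, "p"], method="bonferroni")[1]
        table["p_adjusted"] = adj
        table["significant"] = table["p_adjusted"] < alpha
    else:
        table["significant"] = table["p"] < alpha
    return ComparisonResult(
        test="t_test", table=table, alpha=alpha, n_tests=n_tests,
        extra={"equal_var": equal_var, "correction": correction},
    )


def anova_tukey(
    groups: dict,
    alpha: float = 0.05,
) -> ComparisonResult:
    """One-way ANOVA across groups; Tukey HSD pairwise tests when p < α.

    ``groups`` maps a label (e.g. age in dpf) to the per-larva values of
    one metric at one threshold.
    """
    if len(groups) < 2:
        raise StatsError("anova_tukey needs at least 2 groups")
    labels = list(groups)
    samples = [np.asarray(groups[g], float) for g in labels]
    if any(s.size < 2 for s in samples):
        raise StatsError("every group needs at least 2 larvae")
    f, p = sps.f_oneway(*samples)
    table = pd.DataFrame([{
        "statistic": float(f), "p": float(p),
        **{f"n_{g}": s.size for g, s in zip(labels, samples)},
        "significant": bool(p < alpha),
    }])
    tukey = None
    if p < alpha:
        values = np.concatenate(samples)
        codes = np.concatenate([[str(g)] * s.size for g, s in zip(labels, samples)])
        res = pairwise_tukeyhsd(values, codes, alpha=alpha)
        tukey = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0])
    return ComparisonResult(
        test="anova_tukey", table=table, alpha=alpha, n_tests=1,
        extra={"tukey": tukey, "groups": labels},
    )


def pool_edge_weights(
    datasets: Sequence[TraceDataset | CorrelationNetwork],
) -> np.ndarray:
    """All upper-triangle correlation coefficients pooled across larvae."""
    pools = []
    for d in datasets:
        net = d if isinstance(d, CorrelationNetwork) else correlation_matrix(d)
        pools.append(net.upper_weights())
    if not pools:
        raise StatsError("empty pool")
    return np.concatenate(pools)


def ks_compare(
    group_a: Sequence,
    group_b: Sequence,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Two-sample KS test on pooled pairwise correlation coefficients.

    Each group's sample is the pool of all upper-triangle weights of all
    its larvae; pooled sizes are recorded alongside D and p.
    """
    pa = pool_edge_weights(group_a)
    pb = pool_edge_weights(group_b)
    if pa.size == 0 or pb.size == 0:
        raise StatsError("empty pool")
    res = sps.ks_2samp(pa, pb)
    table = pd.DataFrame([{
        "statistic": float(res.statistic), "p": float(res.pvalue),
        "n_a": pa.size, "n_b": pb.size,
        "significant": bool(res.pvalue < alpha),
    }])
    return ComparisonResult(test="ks", table=table, alpha=alpha, n_tests=1)
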