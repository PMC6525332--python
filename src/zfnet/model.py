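"""Model/Results interface over the full per-larva analysis.

:class:`FunctionalNetwork` is constructed from one larva's trace data
(optionally trimming the initial frames and dropping degenerate ROIs);
``fit()`` runs the whole per-larva pipeline — correlation matrix,
edge-weight CDF, density curve, per-threshold graph metrics, and (when a
surrogate spec is given) surrogate-normalized metrics with ensemble
dispersions — and returns a :class:`FunctionalNetworkResults` carrying
the estimates, their surrogate-ensemble uncertainties, diagnostics and a
``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.iolib.table import SimpleTable

from . import spatial
from .datasets import TraceDataset, clean_traces, trim_initial
from .metrics import degrees, clustering, graph_summary
from .network import (
    DEFAULT_DENSITY_GRID,
    DEFAULT_TAU_GRID,
    correlation_matrix,
    density_curve,
    edge_weight_cdf,
    threshold_binarize,
)
from .surrogates import SurrogateSpec, normalized_metrics


class FunctionalNetwork:
    """Correlation-network model of one larva's resting-state activity.

    Parameters
    ----------
    dataset : TraceDataset
        ΔF/F traces plus ROI coordinates for one larva.
    tau_grid : array-like
        Thresholds for the complex graph metrics (default 0.0–0.7, step 0.1).
    density_grid : array-like
        Thresholds for the density curve (default 0.0–0.9, step 0.1).
    trim_seconds : float
        Initial recording span to discard before analysis (default 60 s,
        the span affected by the scanning-onset fluorescence transient).
    clean : bool
        Drop constant or non-finite traces before correlating.
    """

    def __init__(
        self,
        dataset: TraceDataset,
        tau_grid=DEFAULT_TAU_GRID,
        density_grid=DEFAULT_DENSITY_GRID,
        trim_seconds: float = 60.0,
        clean: bool = True,
    ) -> None:
        if trim_seconds > 0:
            dataset = trim_initial(dataset, trim_seconds)
        self.dropped_rois: list = []
        if clean:
            dataset, self.dropped_rois = clean_traces(dataset)
        self.dataset = dataset
        self.tau_grid = np.asarray(tau_grid, float)
        self.density_grid = np.asarray(density_grid, float)
        self.trim_seconds = trim_seconds

    @classmethod
    def from_dataframe(
        cls,
        traces: pd.DataFrame,
        coords: pd.DataFrame,
        frame_interval: float,
        **kwargs,
    ) -> "FunctionalNetwork":
        """Build the model from a trace table (rows = ROIs) and a
        coordinate table (columns roi_id, x_um, y_um, plane, z_um)."""
        meta = {k: kwargs.pop(k) for k in ("larva_id", "age_dpf", "genotype", "notes")
                if k in kwargs}
        ds = TraceDataset(
            traces=traces.to_numpy(float), coords=coords,
            frame_interval=frame_interval, meta=meta,
        )
        return cls(ds, **kwargs)

    def fit(self, surrogates: SurrogateSpec | None = None) -> "FunctionalNetworkResults":
        """Run the per-larva pipeline; surrogate normalization is included
        when a :class:`SurrogateSpec` is supplied."""
        net = correlation_matrix(self.dataset)
        cdf = edge_weight_cdf(net)
        dens = density_curve(net, self.density_grid)
        dens.larva_id = self.dataset.larva_id
        rows = []
        for tau in self.tau_grid:
            summ = graph_summary(threshold_binarize(net, tau))
            rows.append({"tau": tau, **summ.as_dict()})
        metrics = pd.DataFrame(rows).set_index("tau")
        norm = None
        if surrogates is not None:
            norm = normalized_metrics(
                self.dataset, self.tau_grid, surrogates, net=net)
        return FunctionalNetworkResults(
            model=self, correlations=net, edge_cdf=cdf,
            density=dens, metrics=metrics, normalized=norm,
        )


class FunctionalNetworkResults:
    """Fitted per-larva network measures.

    Attributes
    ----------
    correlations : CorrelationNetwork
    edge_cdf : EdgeWeightDistribution
    density : MetricCurve (over the density grid)
    metrics : DataFrame indexed by τ — density, Cl, L, T, r, diagnostics
    normalized : NormalizedMetrics or None — Cl_norm, L_norm, T_norm, σ
        with surrogate-ensemble means and dispersions
    """

    def __init__(self, model, correlations, edge_cdf, density, metrics,
                 normalized=None) -> None:
        self.model = model
        self.correlations = correlations
        self.edge_cdf = edge_cdf
        self.density = density
        self.metrics = metrics
        self.normalized = normalized

    @property
    def larva_id(self) -> str:
        return self.model.dataset.larva_id

    def metric_curve(self, name: str):
        """A MetricCurve for one column of the metrics (or normalized) table."""
        from .network import MetricCurve
        if name == "density":
            return self.density
        if name in self.metrics.columns:
            return MetricCurve(
                grid=self.metrics.index.to_numpy(),
                values=self.metrics[name].to_numpy(float),
                metric=name, larva_id=self.larva_id,
            )
        if self.normalized is not None and hasattr(self.normalized, name):
            return MetricCurve(
                grid=self.normalized.tau,
                values=np.asarray(getattr(self.normalized, name), float),
                metric=name, larva_id=self.larva_id,
            )
        raise KeyError(f"unknown metric: {name!r}")

    def spatial_map(
        self,
        metric: str = "clustering",
        tau: float = 0.7,
        window_size: float = 20.0,
        stride: float = 5.0,
        normalized_by: "FunctionalNetworkResults | None" = None,
    ) -> spatial.SpatialMap:
        """Sliding-window map of a node metric at one threshold.

        ``metric`` is ``"clustering"`` (per-node clustering coefficient,
        optionally divided by the surrogate-ensemble mean clustering when
        the results carry normalized metrics) or ``"degree_norm"``
        (degree divided by the network's maximum degree).
        """
        bnet = threshold_binarize(self.correlations, tau)
        if metric == "degree_norm":
            values = spatial.normalize_degree_map(degrees(bnet))
        elif metric == "clustering":
            values, _ = clustering(bnet)
            if self.normalized is not None:
                k = int(np.argmin(np.abs(self.normalized.tau - tau)))
                if np.isclose(self.normalized.tau[k], tau):
                    cl_rand = self.normalized.cl_rand[k]
                    if np.isfinite(cl_rand) and cl_rand > 0:
                        values = values / cl_rand
        else:
            raise KeyError(f"unknown map metric: {metric!r}")
        return spatial.node_metric_map(
            self.model.dataset.coords, values,
            window_size=window_size, stride=stride, metric=metric,
        )

    def summary(self) -> SimpleTable:
        """Per-threshold summary table of the fitted network measures."""
        ds = self.model.dataset
        headers = ["tau", "density", "Cl", "L", "T", "r"]
        rows = []
        norm = self.normalized
        if norm is not None:
            headers += ["Cl_norm", "L_norm", "T_norm", "sigma"]
        for i, tau in enumerate(self.metrics.index):
            m = self.metrics.loc[tau]
            row = [f"{tau:.2f}", f"{m.density:.4f}", f"{m.cl:.4f}",
                   f"{m.l:.4f}", f"{m.t:.4f}", f"{m.r:.4f}"]
            if norm is not None:
                row += [f"{norm.cl_norm[i]:.4f}", f"{norm.l_norm[i]:.4f}",
                        f"{norm.t_norm[i]:.4f}", f"{norm.sigma[i]:.4f}"]
            rows.append(row)
        title = (
            f"Functional network: {ds.larva_id or '(unnamed)'} | "
            f"{ds.n_rois} ROIs x {ds.n_frames} frames"
        )
        return SimpleTable(rows, headers=headers, title=title)

    def plot_metrics(self, ax=None):
        """Cl_norm, L_norm and σ (or raw Cl, L, T) versus threshold."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        if self.normalized is not None:
            n = self.normalized
            ax.plot(n.tau, n.cl_norm, "o-", label="Cl_norm")
            ax.plot(n.tau, n.l_norm, "s-", label="L_norm")
            ax.plot(n.tau, n.sigma, "^-", label="sigma")
            ax.axhline(1.0, ls=":", c="k", lw=0.8)
        else:
            m = self.metrics
            ax.plot(m.index, m.cl, "o-", label="Cl")
            ax.plot(m.index, m.t, "s-", label="T")
        ax.set_xlabel("threshold")
        ax.set_ylabel("metric")
        ax.legend()
        ax.set_title(self.larva_id)
        return ax

    def plot_map(self, metric: str = "clustering", tau: float = 0.7, ax=None,
                 **map_kwargs):
        """Render a spatial map of a node metric as a heat map."""
        import matplotlib.pyplot as plt
        smap = self.spatial_map(metric=metric, tau=tau, **map_kwargs)
        if ax is None:
            _, ax = plt.subplots()
        ny, nx = smap.values.shape
        im = ax.imshow(
            smap.values, origin="lower",
            extent=[smap.x0, smap.x0 + nx * smap.stride,
                    smap.y0, smap.y0 + ny * smap.stride],
            interpolation="nearest",
        )
        ax.set_xlabel("x (um)")
        ax.set_ylabel("y (um)")
        ax.set_title(f"{metric} at tau={tau:.2f}")
        plt.colorbar(im, ax=ax)
        return ax
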