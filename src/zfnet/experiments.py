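"""Synthetic validation experiments for the whole pipeline.

These experiments exercise the package end-to-end on generated data with
known ground truth:

* :func:`metric_oracle_check` — graph measures versus brute-force oracles
  on random graphs
* :func:`null_calibration` — surrogate normalization on i.i.d. Gaussian
  traces, where every normalized metric should be ≈ 1 wherever it is
  defined, plus exact density matching
* :func:`small_world_recovery` — assembly-structured larvae should show
  σ > 1 and elevated Cl_norm relative to matched unstructured controls
* :func:`group_contrast` — a planted burst-participation shift between
  two simulated groups should be detected by the pooled-edge-weight KS
  test and by per-threshold t tests on Cl_norm

Sample sizes are desk-scale by design (tens of larvae, tens of
surrogates); the qualitative directions they probe do not depend on the
ensemble being large.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import oracles
from .datasets import COORD_COLUMNS, TraceDataset
from .metrics import (
    assortativity,
    characteristic_path_length,
    clustering,
    transitivity,
)
from .network import BinaryNetwork, MetricCurve, correlation_matrix
from .simulate import SimulationConfig, simulate_group, simulate_larva
from .stats import ks_compare, per_threshold_ttest
from .surrogates import SurrogateSpec, matched_threshold, normalized_metrics


def random_graphs(n_graphs: int, seed: int, n_max: int = 12):
    """Seeded Erdős–Rényi binary networks with 2 ≤ n ≤ n_max."""
    rng = np.random.default_rng(seed)
    graphs = []
    for _ in range(n_graphs):
        n = int(rng.integers(2, n_max + 1))
        p = float(rng.uniform(0.1, 0.9))
        a = (rng.random((n, n)) < p)
        a = np.triu(a, k=1)
        a = (a | a.T).astype(np.int8)
        graphs.append(BinaryNetwork(adjacency=a, threshold=np.nan))
    return graphs


def metric_oracle_check(n_graphs: int = 200, seed: int = 0, n_max: int = 12) -> dict:
    """Largest |fast − brute-force| discrepancy over Cl, L, T, r.

    NaN agreement (both undefined) counts as a discrepancy of 0; one-sided
    NaN counts as infinite.
    """
    def diff(a: float, b: float) -> float:
        if np.isnan(a) and np.isnan(b):
            return 0.0
        if np.isnan(a) or np.isnan(b):
            return np.inf
        return abs(a - b)

    worst = {"cl": 0.0, "l": 0.0, "t": 0.0, "r": 0.0, "c_node": 0.0}
    for bnet in random_graphs(n_graphs, seed, n_max):
        a = bnet.adjacency
        c_fast, cl_fast = clustering(bnet)
        c_ref, cl_ref = oracles.brute_clustering(a)
        worst["c_node"] = max(worst["c_node"], float(np.abs(c_fast - c_ref).max()))
        worst["cl"] = max(worst["cl"], diff(cl_fast, cl_ref))
        l_fast, u_fast = characteristic_path_length(bnet)
        l_ref, u_ref = oracles.brute_path_length(a)
        worst["l"] = max(worst["l"], diff(l_fast, l_ref),
                         0.0 if u_fast == u_ref else np.inf)
        worst["t"] = max(worst["t"], diff(transitivity(bnet),
                                          oracles.brute_transitivity(a)))
        if bnet.n_edges > 0:
            worst["r"] = max(worst["r"], diff(assortativity(bnet),
                                              oracles.brute_assortativity(a)))
    worst["max"] = max(worst.values())
    worst["n_graphs"] = n_graphs
    return worst


def gaussian_noise_dataset(n_rois: int, n_frames: int, seed: int) -> TraceDataset:
    """i.i.d. standard-Gaussian traces — the fully unstructured null."""
    rng = np.random.default_rng(seed)
    coords = pd.DataFrame({
        "roi_id": np.arange(n_rois),
        "x_um": rng.uniform(0, 500, n_rois),
        "y_um": rng.uniform(0, 500, n_rois),
        "plane": np.zeros(n_rois, dtype=int),
        "z_um": np.zeros(n_rois),
    }, columns=COORD_COLUMNS)
    return TraceDataset(
        traces=rng.standard_normal((n_rois, n_frames)),
        coords=coords, frame_interval=1.0,
        meta={"larva_id": f"noise{seed}", "genotype": "noise", "age_dpf": 0},
    )


def null_calibration(
    n_datasets: int = 20,
    n_rois: int = 60,
    n_frames: int = 600,
    n_surrogates: int = 25,
    tau_grid=(0.1, 0.2, 0.3),
    seed: int = 0,
) -> pd.DataFrame:
    """Normalized metrics on pure-noise datasets, one row per (dataset, τ).

    On a correctly calibrated normalization every defined ratio is ≈ 1;
    the returned frame also carries the worst density-matching error (in
    pair units) so exact-rank matching can be asserted.
    """
    tau_grid = np.asarray(tau_grid, float)
    rows = []
    for d in range(n_datasets):
        ds = gaussian_noise_dataset(n_rois, n_frames, seed + 7919 * (d + 1))
        spec = SurrogateSpec(n_surrogates=n_surrogates, seed=seed + 104729 * (d + 1))
        norm = normalized_metrics(ds, tau_grid, spec)
        n_pairs = n_rois * (n_rois - 1) // 2
        err_pairs = np.abs(norm.achieved_densities - norm.density[None, :]) * n_pairs
        for k, tau in enumerate(tau_grid):
            rows.append({
                "dataset": d, "tau": tau,
                "density": norm.density[k],
                "cl_norm": norm.cl_norm[k], "l_norm": norm.l_norm[k],
                "t_norm": norm.t_norm[k], "sigma": norm.sigma[k],
                "n_surrogates_used": norm.n_surrogates_used[k],
                "max_density_error_pairs": float(np.nanmax(err_pairs[:, k])),
            })
    return pd.DataFrame(rows)


def structured_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Assembly-structured larva: 5 assemblies of 20 in 100 ROIs."""
    cfg = SimulationConfig(
        n_rois=100, n_assemblies=5, assembly_sizes=(20,) * 5,
        burst_participation=0.8, seed=seed,
    )
    return replace(cfg, **overrides)


def unstructured_control(cfg: SimulationConfig) -> SimulationConfig:
    """Matched control: assemblies removed, background rate raised by the
    per-ROI burst-driven spike rate so total activity matches."""
    extra = cfg.burst_rate * cfg.burst_participation
    return replace(
        cfg, n_assemblies=0, assembly_sizes=(),
        background_rate=cfg.background_rate + extra,
    )


def small_world_recovery(
    n_replicates: int = 10,
    n_surrogates: int = 20,
    tau_grid=(0.3, 0.4, 0.5, 0.6, 0.7),
    seed: int = 0,
    trim_seconds: float = 60.0,
) -> pd.DataFrame:
    """Structured larvae vs matched unstructured controls.

    The control for each replicate is a circular-shift randomization of
    the same structured larva: identical per-trace marginal statistics
    and autocorrelation, no cross-trace alignment.  Unstructured data
    have (essentially) no edge weights above 0.3, so the control is
    evaluated at *matched density*: for each evaluable structured cell
    the control is thresholded at its own τ′ reproducing the structured
    network's density — the same matching device the surrogate
    normalization uses — where its normalized clustering is ≈ 1.

    A τ cell is evaluable when its metrics are defined and the network
    is super-critical (mean degree ≥ 1, i.e. density ≥ 1/(n−1)); below
    the giant-component threshold the graph is fragmented dust and ratio
    metrics are dominated by a handful of edges.
    """
    from .datasets import clean_traces, trim_initial
    from .surrogates import randomize_traces

    tau_grid = np.asarray(tau_grid, float)
    rows = []
    for rep in range(n_replicates):
        rep_seed = seed + 1009 * (rep + 1)
        ds, _ = simulate_larva(structured_config(seed=rep_seed))
        ds = trim_initial(ds, trim_seconds)
        ds, _ = clean_traces(ds)
        s = normalized_metrics(
            ds, tau_grid,
            SurrogateSpec(n_surrogates=n_surrogates, seed=rep_seed + 500_000))
        evaluable = (np.isfinite(s.sigma) & np.isfinite(s.cl_norm)
                     & (s.density >= 1.0 / (ds.n_rois - 1)))
        ctrl = randomize_traces(ds, seed=rep_seed + 600_000)
        ctrl_net = correlation_matrix(ctrl)
        c_cl = np.full(tau_grid.size, np.nan)
        if evaluable.any():
            ctrl_taus = [matched_threshold(ctrl_net, d)
                         for d in s.density[evaluable]]
            c = normalized_metrics(
                ctrl, ctrl_taus,
                SurrogateSpec(n_surrogates=n_surrogates, seed=rep_seed + 700_000),
                net=ctrl_net)
            c_cl[evaluable] = c.cl_norm
        comparable = evaluable & np.isfinite(c_cl)
        rows.append({
            "replicate": rep,
            "sigma_mean": float(np.mean(s.sigma[evaluable]))
            if evaluable.any() else np.nan,
            "sigma_gt_1_all_tau": bool(
                evaluable.any() and (s.sigma[evaluable] > 1).all()),
            "cl_norm_structured_mean": float(np.mean(s.cl_norm[evaluable]))
            if evaluable.any() else np.nan,
            "cl_norm_control_mean": float(np.mean(c_cl[comparable]))
            if comparable.any() else np.nan,
            "cl_norm_exceeds_control": bool(
                comparable.any()
                and (s.cl_norm[comparable] > c_cl[comparable]).all()),
            "n_evaluable_tau": int(evaluable.sum()),
        })
    return pd.DataFrame(rows)


def group_contrast(
    n_replicates: int = 10,
    n_larvae: int = 8,
    participation_delta: float = 0.2,
    n_surrogates: int = 20,
    tau_grid=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7),
    high_tau: float = 0.4,
    seed: int = 0,
    trim_seconds: float = 60.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Planted participation shift between two simulated groups.

    Baseline larvae use participation 0.7; the shifted group applies
    +``participation_delta``.  Per replicate: KS p on pooled edge weights
    and the per-threshold t test on Cl_norm, with detection defined as
    significance at ≥ 1 threshold ≥ ``high_tau``.  The default
    ``high_tau`` of 0.4 is the top of the range where baseline-group
    networks still carry enough edges for Cl_norm to be defined; above it
    cells go missing because the graphs are empty, not because the effect
    is absent.
    """
    from .datasets import clean_traces, trim_initial

    tau_grid = np.asarray(tau_grid, float)
    base_cfg = structured_config(burst_participation=0.7)
    rows = []
    for rep in range(n_replicates):
        rep_seed = seed + 30011 * (rep + 1)
        groups = {}
        nets = {}
        for gi, (regime, shift) in enumerate(
            (("baseline", None),
             ("shifted", {"participation_delta": participation_delta}))):
            sims = simulate_group(base_cfg, n_larvae, regime=regime,
                                  shift_params=shift,
                                  base_seed=rep_seed + 100 * gi)
            curves, pools = [], []
            for li, (ds, _) in enumerate(sims):
                ds = trim_initial(ds, trim_seconds)
                ds, _ = clean_traces(ds)
                net = correlation_matrix(ds)
                pools.append(net)
                spec = SurrogateSpec(
                    n_surrogates=n_surrogates,
                    seed=rep_seed + 1_000_000 * (gi + 1) + 1000 * li)
                norm = normalized_metrics(ds, tau_grid, spec, net=net)
                curves.append(MetricCurve(grid=tau_grid, values=norm.cl_norm,
                                          metric="cl_norm",
                                          larva_id=ds.larva_id))
            groups[regime] = curves
            nets[regime] = pools
        ks = ks_compare(nets["baseline"], nets["shifted"], alpha=alpha)
        tt = per_threshold_ttest(groups["baseline"], groups["shifted"],
                                 alpha=alpha)
        high = tt.table[tt.table.tau >= high_tau - 1e-9]
        rows.append({
            "replicate": rep,
            "ks_p": float(ks.table["p"].iloc[0]),
            "ks_detected": bool(ks.table["p"].iloc[0] < alpha),
            "t_min_p_high_tau": float(np.nanmin(high["p"]))
            if np.isfinite(high["p"]).any() else np.nan,
            "t_detected": bool((high["p"] < alpha).any()),
        })
    return pd.DataFrame(rows)
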