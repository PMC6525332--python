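"""Time-series-randomized surrogate networks and normalized graph metrics.

A surrogate larva is the same set of traces with cross-trace temporal
alignment destroyed: each trace is independently circularly shifted
(default; preserves the trace's marginal distribution and autocorrelation
exactly) or Fourier phase-randomized (preserves the amplitude spectrum).
Surrogate correlation networks are thresholded not at τ but at a matched
threshold τ′ chosen so the surrogate's density equals the experimental
network's density at τ — the null then differs from the data only in its
correlation *structure*, not in edge count.

Normalized metrics divide each experimental measure by the surrogate
ensemble mean at matched density: Cl_norm = Cl / Cl_rand,
L_norm = L / L_rand, T_norm = T / T_rand, and small-worldness
σ = Cl_norm / L_norm (σ > 1 indicates small-world organization).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datasets import TraceDataset
from .metrics import characteristic_path_length, clustering, transitivity
from .network import (
    BinaryNetwork,
    CorrelationNetwork,
    correlation_matrix,
    threshold_binarize,
)

METHODS = ("circular_shift", "phase_randomize")


@dataclass
class SurrogateSpec:
    """Ensemble parameters: randomization method, size, seeding.

    ``n_surrogates`` defaults to 100.  Surrogate i uses seed
    ``seed + i`` so ensembles are reproducible and extensible.  A τ cell
    of the ensemble mean is reported missing (NaN) when more than
    ``max_undefined_fraction`` of surrogates are undefined there.
    """

    method: str = "circular_shift"
    n_surrogates: int = 100
    seed: int = 0
    density_tolerance: float | None = None  # default 0.5 / n_pairs, set at run time
    max_undefined_fraction: float = 0.5

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown surrogate method: {self.method!r}")
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")
        if self.density_tolerance is not None and self.density_tolerance < 0:
            raise ValueError("density_tolerance must be >= 0")


@dataclass
class NormalizedMetrics:
    """Experimental, surrogate-ensemble, and normalized metrics per τ."""

    tau: np.ndarray
    density: np.ndarray
    cl: np.ndarray
    l: np.ndarray
    t: np.ndarray
    cl_rand: np.ndarray
    l_rand: np.ndarray
    t_rand: np.ndarray
    cl_rand_sd: np.ndarray
    l_rand_sd: np.ndarray
    t_rand_sd: np.ndarray
    cl_norm: np.ndarray
    l_norm: np.ndarray
    t_norm: np.ndarray
    sigma: np.ndarray
    n_surrogates_used: np.ndarray       # per τ, min over the three metrics
    matched_thresholds: np.ndarray      # (n_surrogates, n_tau)
    achieved_densities: np.ndarray      # (n_surrogates, n_tau)
    method: str = "circular_shift"
    seed: int = 0
    larva_id: str = ""
    extra: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (τ, metric)."""
        rows = []
        for name in ("density", "cl", "l", "t", "cl_rand", "l_rand", "t_rand",
                     "cl_norm", "l_norm", "t_norm", "sigma"):
            vals = getattr(self, name)
            for k, tau in enumerate(self.tau):
                rows.append({
                    "larva_id": self.larva_id, "tau": tau, "metric": name,
                    "value": vals[k],
                    "n_surrogates_used": int(self.n_surrogates_used[k]),
                    "method": self.method, "seed": self.seed,
                })
        return pd.DataFrame(rows)


def randomize_traces(
    dataset: TraceDataset,
    method: str = "circular_shift",
    seed: int | np.random.Generator = 0,
) -> TraceDataset:
    """Randomize each trace independently, destroying cross-trace alignment.

    circular_shift
        Rotate each trace by an offset drawn uniformly from
        1..n_frames−1.  A rotation is a permutation, so the marginal
        distribution and (circular) autocorrelation of every trace are
        preserved exactly.
    phase_randomize
        Replace the phases of the trace's Fourier coefficients with
        uniform random phases, keeping the amplitude spectrum.
    """
    if method not in METHODS:
        raise ValueError(f"unknown surrogate method: {method!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    traces = dataset.traces
    n, n_frames = traces.shape
    if method == "circular_shift":
        offsets = rng.integers(1, n_frames, size=n)
        out = np.empty_like(traces)
        for i in range(n):
            out[i] = np.roll(traces[i], offsets[i])
    else:
        spec = np.fft.rfft(traces, axis=1)
        n_freq = spec.shape[1]
        phases = rng.uniform(0.0, 2.0 * np.pi, size=(n, n_freq))
        phases[:, 0] = 0.0
        if n_frames % 2 == 0:
            phases[:, -1] = 0.0  # Nyquist bin must stay real
        out = np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n=n_frames, axis=1)
    return replace(dataset, traces=out)


def matched_threshold(surrogate_net: CorrelationNetwork, target_density: float) -> float:
    """Threshold τ′ at which the surrogate matches a target density.

    With n_pairs distinct weights, k = round(target_density × n_pairs)
    edges should survive; τ′ is placed at the midpoint between the k-th
    and (k+1)-th largest weights so exactly k edges exceed it strictly.
    Ties at the boundary resolve toward fewer edges.  The achieved density
    k / n_pairs is within 0.5 / n_pairs of the target by construction.
    """
    if not 0.0 <= target_density <= 1.0:
        raise ValueError("target_density must be in [0, 1]")
    w = surrogate_net.upper_weights()
    n_pairs = w.size
    k = int(round(target_density * n_pairs))
    if k <= 0:
        return float(w.max())
    if k >= n_pairs:
        # just below the minimum weight, clamped into the valid range
        return float(max(-1.0, np.nextafter(w.min(), -np.inf)))
    ws = np.sort(w)[::-1]
    a, b = ws[k - 1], ws[k]
    if a == b:  # tie: keep only weights strictly above the tied value
        return float(a)
    return float(0.5 * (a + b))


def _metrics_at(bnet: BinaryNetwork) -> tuple[float, float, float]:
    _, cl = clustering(bnet)
    l, _ = characteristic_path_length(bnet)
    t = transitivity(bnet)
    return cl, l, t


def normalized_metrics(
    dataset: TraceDataset,
    tau_grid,
    spec: SurrogateSpec | None = None,
    net: CorrelationNetwork | None = None,
) -> NormalizedMetrics:
    """Surrogate-normalized Cl, L, T and small-worldness σ over a τ grid.

    For each τ the experimental network's density is computed, and every
    surrogate is thresholded at its own matched τ′ reproducing that
    density.  Ensemble means use surrogates with defined values only;
    a cell is missing if more than half the ensemble is undefined there.
    Deterministic given ``spec.seed``.

    Pass ``net`` to reuse a precomputed experimental correlation network.
    """
    spec = spec or SurrogateSpec()
    spec.validate()
    tau_grid = np.asarray(tau_grid, dtype=float)
    if net is None:
        net = correlation_matrix(dataset)
    n_tau = tau_grid.size
    n_pairs = net.n_pairs
    tol = spec.density_tolerance
    if tol is None:
        tol = 0.5 / n_pairs

    density = np.empty(n_tau)
    cl = np.empty(n_tau)
    l = np.empty(n_tau)
    t = np.empty(n_tau)
    for k, tau in enumerate(tau_grid):
        bnet = threshold_binarize(net, tau)
        density[k] = bnet.source_density
        cl[k], l[k], t[k] = _metrics_at(bnet)

    ns = spec.n_surrogates
    s_cl = np.full((ns, n_tau), np.nan)
    s_l = np.full((ns, n_tau), np.nan)
    s_t = np.full((ns, n_tau), np.nan)
    taup = np.full((ns, n_tau), np.nan)
    ach = np.full((ns, n_tau), np.nan)
    for s in range(ns):
        surr = randomize_traces(dataset, method=spec.method, seed=spec.seed + s)
        snet = correlation_matrix(surr)
        for k in range(n_tau):
            tp = matched_threshold(snet, density[k])
            sb = threshold_binarize(snet, tp)
            taup[s, k] = tp
            ach[s, k] = sb.source_density
            if abs(sb.source_density - density[k]) > tol + 1e-12:
                raise RuntimeError(
                    f"surrogate density {sb.source_density:.6f} misses target "
                    f"{density[k]:.6f} beyond tolerance {tol:.6f}")
            s_cl[s, k], s_l[s, k], s_t[s, k] = _metrics_at(sb)

    def ensemble(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        defined = np.isfinite(x)
        count = defined.sum(axis=0)
        ok = (count >= 1) & (
            count > (1.0 - spec.max_undefined_fraction) * ns - 1e-12)
        filled = np.where(defined, x, 0.0)
        denom = np.maximum(count, 1)
        mean = np.where(ok, filled.sum(axis=0) / denom, np.nan)
        dev2 = np.where(defined, (x - np.where(ok, mean, 0.0)[None, :]) ** 2, 0.0)
        sd = np.where(
            ok & (count > 1),
            np.sqrt(dev2.sum(axis=0) / np.maximum(count - 1, 1)),
            np.nan,
        )
        return mean, sd, count

    cl_rand, cl_sd, cl_count = ensemble(s_cl)
    l_rand, l_sd, l_count = ensemble(s_l)
    t_rand, t_sd, t_count = ensemble(s_t)

    with np.errstate(invalid="ignore", divide="ignore"):
        cl_norm = cl / cl_rand
        l_norm = l / l_rand
        t_norm = t / t_rand
        sigma = cl_norm / l_norm
    for arr in (cl_norm, l_norm, t_norm, sigma):
        arr[~np.isfinite(arr)] = np.nan

    return NormalizedMetrics(
        tau=tau_grid, density=density, cl=cl, l=l, t=t,
        cl_rand=cl_rand, l_rand=l_rand, t_rand=t_rand,
        cl_rand_sd=cl_sd, l_rand_sd=l_sd, t_rand_sd=t_sd,
        cl_norm=cl_norm, l_norm=l_norm, t_norm=t_norm, sigma=sigma,
        n_surrogates_used=np.minimum(np.minimum(cl_count, l_count), t_count),
        matched_thresholds=taup, achieved_densities=ach,
        method=spec.method, seed=spec.seed, larva_id=dataset.larva_id,
    )


def small_worldness(norm: NormalizedMetrics) -> np.ndarray:
    """Per-τ small-worldness σ = Cl_norm / L_norm; σ > 1 is small-world."""
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma = norm.cl_norm / norm.l_norm
    sigma[~np.isfinite(sigma)] = np.nan
    return sigma
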