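"""Synthetic multiplane calcium-imaging data with planted assembly structure.

The generator emulates the resting-state regime seen in larval zebrafish
two-photon recordings: mostly quiet ROIs with occasional background
transients, punctuated by assembly-wide synchronous bursts, rendered
through a slow GCaMP6s-like exponential kernel and corrupted by Gaussian
read noise.  Every parameter maps to an observable:

* background activity   — homogeneous Poisson spikes per ROI
* synchrony             — per-assembly Poisson burst events; each member
                          joins each event independently with probability
                          ``burst_participation``
* indicator kinetics    — causal kernel ``exp(-t / decay_tau)``, spikes
                          binned to the frame grid before convolution
* measurement noise     — i.i.d. Gaussian, ``noise_sd`` ΔF/F units

Ground truth (assembly labels, spike times, burst event times) is returned
alongside the dataset so downstream inference can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .datasets import COORD_COLUMNS, TraceDataset


class SimulationConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


@dataclass
class SimulationConfig:
    """Parameters of one simulated larva.

    Defaults emulate a single-plane slice of the acquisition geometry used
    for larval zebrafish resting-state imaging — order 10^2 ROIs recorded
    for 15 min at 1 frame/s — with assembly-driven synchronous bursts and
    a slow (GCaMP6s-like) indicator.
    """

    n_rois: int = 100
    n_assemblies: int = 5
    assembly_sizes: tuple[int, ...] | None = None  # default: equal split of 20
    frame_interval: float = 1.0      # s
    duration: float = 900.0          # s (15 min)
    background_rate: float = 0.04    # spikes/s per ROI
    burst_rate: float = 0.05         # events/s per assembly
    burst_participation: float = 0.8
    decay_tau: float = 3.5           # s, indicator decay
    amplitude_jitter: float = 0.3    # CV of per-spike amplitude
    noise_sd: float = 0.05           # ΔF/F units
    n_planes: int = 12
    plane_spacing: float = 10.0      # μm
    field_size: tuple[float, float] = (500.0, 500.0)  # μm
    seed: int = 0

    def resolved_assembly_sizes(self) -> tuple[int, ...]:
        if self.n_assemblies == 0:
            return ()
        if self.assembly_sizes is None:
            size = min(20, self.n_rois // max(self.n_assemblies, 1))
            return (size,) * self.n_assemblies
        return tuple(self.assembly_sizes)

    def validate(self) -> None:
        if self.n_rois < 1:
            raise SimulationConfigError("n_rois must be >= 1")
        if self.n_assemblies < 0:
            raise SimulationConfigError("n_assemblies must be >= 0")
        sizes = self.resolved_assembly_sizes()
        if len(sizes) != self.n_assemblies:
            raise SimulationConfigError(
                "assembly_sizes length must equal n_assemblies")
        if any(s < 1 for s in sizes):
            raise SimulationConfigError("assembly_sizes entries must be >= 1")
        if sum(sizes) > self.n_rois:
            raise SimulationConfigError(
                f"assembly_sizes sum to {sum(sizes)} > n_rois={self.n_rois}")
        if not self.frame_interval > 0:
            raise SimulationConfigError("frame_interval must be > 0")
        if int(np.floor(self.duration / self.frame_interval)) < 2:
            raise SimulationConfigError(
                "duration must allow n_frames = floor(duration/frame_interval) >= 2")
        for name in ("background_rate", "burst_rate", "amplitude_jitter",
                     "noise_sd", "plane_spacing"):
            if getattr(self, name) < 0:
                raise SimulationConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.burst_participation <= 1.0:
            raise SimulationConfigError("burst_participation must be in [0, 1]")
        if not self.decay_tau > 0:
            raise SimulationConfigError("decay_tau must be > 0")
        if self.n_planes < 1:
            raise SimulationConfigError("n_planes must be >= 1")
        if len(self.field_size) != 2 or any(s <= 0 for s in self.field_size):
            raise SimulationConfigError("field_size must be two positive extents")

    @property
    def n_frames(self) -> int:
        return int(np.floor(self.duration / self.frame_interval))


@dataclass
class GroundTruth:
    """Planted structure of a simulated larva.

    ``assembly_label`` is one integer per ROI (−1 for unassigned background
    ROIs); ``spike_times`` lists every spike time per ROI (background and
    burst-driven); ``burst_event_times`` lists event times per assembly.
    """

    assembly_label: np.ndarray
    spike_times: list
    burst_event_times: list
    config: SimulationConfig = field(repr=False, default=None)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "assembly_label": np.asarray(self.assembly_label).tolist(),
            "spike_times": [list(map(float, s)) for s in self.spike_times],
            "burst_event_times": [list(map(float, e)) for e in self.burst_event_times],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            assembly_label=np.asarray(payload["assembly_label"], dtype=int),
            spike_times=payload["spike_times"],
            burst_event_times=payload["burst_event_times"],
        )


def _poisson_times(rng: np.random.Generator, rate: float, duration: float) -> np.ndarray:
    """Event times of a homogeneous Poisson process on [0, duration)."""
    if rate <= 0:
        return np.empty(0)
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def simulate_larva(config: SimulationConfig) -> tuple[TraceDataset, GroundTruth]:
    """Simulate one larva: ΔF/F traces, ROI coordinates, and ground truth.

    Deterministic given ``config.seed``.  ROIs are placed uniformly in the
    field and assigned to planes round-robin (z = plane × plane_spacing).
    Spikes are binned to the frame grid, convolved with the causal
    exponential kernel, amplitude-jittered per spike, and read noise is
    added last; the per-trace baseline is 0.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, n_frames = config.n_rois, config.n_frames
    dt = config.frame_interval

    # (1) geometry
    x = rng.uniform(0.0, config.field_size[0], size=n)
    y = rng.uniform(0.0, config.field_size[1], size=n)
    plane = np.arange(n) % config.n_planes
    z = plane * config.plane_spacing
    coords = pd.DataFrame(
        {"roi_id": np.arange(n), "x_um": x, "y_um": y, "plane": plane, "z_um": z},
        columns=COORD_COLUMNS,
    )

    # assembly membership: first ROIs filled in order, remainder background
    labels = np.full(n, -1, dtype=int)
    start = 0
    for a, size in enumerate(config.resolved_assembly_sizes()):
        labels[start:start + size] = a
        start += size

    # (2) background spikes per ROI
    spike_times: list[list[float]] = [
        list(_poisson_times(rng, config.background_rate, config.duration))
        for _ in range(n)
    ]

    # (3) assembly burst events; members join independently
    burst_event_times: list[list[float]] = []
    for a in range(config.n_assemblies):
        events = _poisson_times(rng, config.burst_rate, config.duration)
        burst_event_times.append(list(events))
        members = np.flatnonzero(labels == a)
        for t in events:
            joins = rng.random(members.size) < config.burst_participation
            for i in members[joins]:
                spike_times[i].append(float(t))

    # (4) bin to frames, jitter amplitudes, convolve with exp(-t/tau)
    drive = np.zeros((n, n_frames))
    for i, times in enumerate(spike_times):
        spike_times[i] = sorted(times)
        if not times:
            continue
        frames = np.floor(np.asarray(spike_times[i]) / dt).astype(int)
        frames = frames[frames < n_frames]
        amps = np.ones(frames.size)
        if config.amplitude_jitter > 0:
            amps *= np.clip(
                1.0 + config.amplitude_jitter * rng.standard_normal(frames.size),
                0.0, None)
        np.add.at(drive[i], frames, amps)
    alpha = np.exp(-dt / config.decay_tau)
    traces = lfilter([1.0], [1.0, -alpha], drive, axis=1)

    # (5) read noise
    if config.noise_sd > 0:
        traces = traces + config.noise_sd * rng.standard_normal(traces.shape)

    dataset = TraceDataset(
        traces=traces,
        coords=coords,
        frame_interval=dt,
        meta={"larva_id": f"sim{config.seed}", "age_dpf": 0,
              "genotype": "sim", "notes": ""},
    )
    truth = GroundTruth(
        assembly_label=labels,
        spike_times=spike_times,
        burst_event_times=burst_event_times,
        config=config,
    )
    return dataset, truth


def shifted_config(
    config: SimulationConfig,
    participation_delta: float = 0.0,
    rate_delta: float = 0.0,
) -> SimulationConfig:
    """Apply a planted group shift to a baseline configuration."""
    new_p = config.burst_participation + participation_delta
    if not 0.0 <= new_p <= 1.0:
        raise SimulationConfigError(
            f"burst_participation {config.burst_participation} + delta "
            f"{participation_delta} leaves [0, 1]")
    new_rate = config.burst_rate + rate_delta
    if new_rate < 0:
        raise SimulationConfigError("burst_rate shift produces a negative rate")
    return replace(config, burst_participation=new_p, burst_rate=new_rate)


def simulate_group(
    config: SimulationConfig,
    n_larvae: int,
    regime: str = "baseline",
    shift_params: dict | None = None,
    base_seed: int = 0,
) -> list[tuple[TraceDataset, GroundTruth]]:
    """Simulate a group of larvae under one regime.

    ``regime`` is "baseline" (config as given) or "shifted"
    (``shift_params`` with keys ``participation_delta`` / ``rate_delta``
    applied first).  Larva ``i`` uses seed ``base_seed + i`` so groups are
    independently reproducible; the regime is recorded as the genotype
    label in each dataset's metadata.
    """
    if n_larvae < 2:
        raise SimulationConfigError("n_larvae must be >= 2")
    if regime not in ("baseline", "shifted"):
        raise SimulationConfigError(f"unknown regime label: {regime!r}")
    if regime == "shifted":
        shift_params = shift_params or {}
        config = shifted_config(
            config,
            participation_delta=shift_params.get("participation_delta", 0.0),
            rate_delta=shift_params.get("rate_delta", 0.0),
        )
    out = []
    for i in range(n_larvae):
        cfg = replace(config, seed=base_seed + i)
        ds, truth = simulate_larva(cfg)
        ds.meta.update(
            larva_id=f"{regime}_{i:02d}", genotype=regime, age_dpf=0,
        )
        out.append((ds, truth))
    return out
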