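"""Synthetic calcium-data generator: contracts, determinism, planted structure."""

import numpy as np
import pytest

from zfnet import (
    SimulationConfig,
    clean_traces,
    correlation_matrix,
    simulate_group,
    simulate_larva,
)
from zfnet.simulate import SimulationConfigError, shifted_config


def small_config(**kw):
    base = dict(n_rois=20, n_assemblies=1, assembly_sizes=(10,), duration=300.0,
                seed=0)
    base.update(kw)
    return SimulationConfig(**base)


class TestContracts:
    def test_shapes(self):
        cfg = SimulationConfig(n_rois=100, duration=900, frame_interval=1, seed=7)
        ds, gt = simulate_larva(cfg)
        assert ds.traces.shape == (100, 900)
        assert len(ds.coords) == 100
        assert gt.assembly_label.shape == (100,)
        assert len(gt.spike_times) == 100

    def test_invalid_config_names_field(self):
        with pytest.raises(SimulationConfigError, match="burst_participation"):
            simulate_larva(small_config(burst_participation=1.5))
        with pytest.raises(SimulationConfigError, match="noise_sd"):
            simulate_larva(small_config(noise_sd=-0.1))
        with pytest.raises(SimulationConfigError, match="assembly_sizes"):
            simulate_larva(small_config(assembly_sizes=(25,)))

    def test_plane_assignment(self):
        cfg = SimulationConfig(n_rois=24, n_planes=12, plane_spacing=10.0, seed=1)
        ds, _ = simulate_larva(cfg)
        assert sorted(ds.coords["plane"].unique()) == list(range(12))
        assert np.allclose(ds.coords["z_um"], ds.coords["plane"] * 10.0)

    def test_burst_spikes_recorded_in_event_list(self):
        cfg = small_config(background_rate=0.0, burst_participation=1.0, seed=3)
        _, gt = simulate_larva(cfg)
        events = set(np.round(gt.burst_event_times[0], 9))
        members = np.flatnonzero(gt.assembly_label == 0)
        for i in members:
            assert set(np.round(gt.spike_times[i], 9)) <= events


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = small_config(seed=42)
        a, _ = simulate_larva(cfg)
        b, _ = simulate_larva(cfg)
        assert np.array_equal(a.traces, b.traces)
        assert a.coords.equals(b.coords)

    def test_different_seed_differs(self):
        a, _ = simulate_larva(small_config(seed=1))
        b, _ = simulate_larva(small_config(seed=2))
        assert not np.array_equal(a.traces, b.traces)


class TestKernel:
    def test_noiseless_trace_equals_kernel_sum(self):
        # with no noise/jitter each trace is exactly the spike train
        # convolved with exp(−t/τ); rebuild it independently from ground truth
        cfg = small_config(noise_sd=0.0, amplitude_jitter=0.0,
                           background_rate=0.05, burst_rate=0.02, seed=5)
        ds, gt = simulate_larva(cfg)
        alpha = np.exp(-cfg.frame_interval / cfg.decay_tau)
        n_frames = ds.n_frames
        for i in range(ds.n_rois):
            expected = np.zeros(n_frames)
            for t_spike in gt.spike_times[i]:
                f = int(t_spike // cfg.frame_interval)
                if f < n_frames:
                    expected[f:] += alpha ** np.arange(n_frames - f)
            assert np.allclose(ds.traces[i], expected, atol=1e-10)

    def test_fluorescence_integral_per_spike(self):
        # total fluorescence of one early spike ≈ τ/dt within discretization
        cfg = small_config(n_rois=2, n_assemblies=1, assembly_sizes=(2,),
                           noise_sd=0.0, amplitude_jitter=0.0,
                           background_rate=0.0, burst_rate=0.01,
                           burst_participation=1.0, duration=600.0, seed=8)
        ds, gt = simulate_larva(cfg)
        n_spikes = len(gt.spike_times[0])
        assert n_spikes > 0
        total = ds.traces[0].sum()
        ratio = total / n_spikes / (cfg.decay_tau / cfg.frame_interval)
        # geometric sum 1/(1−e^(−dt/τ)) vs τ/dt: relative error ≲ dt/(2τ)
        assert ratio == pytest.approx(1.0, rel=cfg.frame_interval / cfg.decay_tau)

    def test_identical_traces_when_deterministic(self):
        cfg = SimulationConfig(
            n_rois=2, n_assemblies=1, assembly_sizes=(2,), noise_sd=0.0,
            amplitude_jitter=0.0, background_rate=0.0, burst_participation=1.0,
            seed=4)
        ds, _ = simulate_larva(cfg)
        assert np.array_equal(ds.traces[0], ds.traces[1])
        assert np.corrcoef(ds.traces[0], ds.traces[1])[0, 1] == pytest.approx(1.0)


class TestPlantedStructure:
    def test_within_assembly_exceeds_between(self):
        # expected gap ≈ 0.44 (range 0.34–0.51 over 20 seeds at these settings)
        cfg = SimulationConfig(
            n_rois=60, n_assemblies=2, assembly_sizes=(30, 30), burst_rate=0.05,
            burst_participation=0.9, noise_sd=0.05, seed=11)
        ds, gt = simulate_larva(cfg)
        ds, _ = clean_traces(ds)
        net = correlation_matrix(ds)
        iu = np.triu_indices(net.n, 1)
        same = gt.assembly_label[iu[0]] == gt.assembly_label[iu[1]]
        gap = net.weights[iu][same].mean() - net.weights[iu][~same].mean()
        assert gap > 0.2

    def test_null_regime_uncorrelated(self):
        cfg = SimulationConfig(n_rois=40, n_assemblies=0, assembly_sizes=(),
                               background_rate=0.1, noise_sd=0.05,
                               duration=900.0, seed=9)
        ds, _ = simulate_larva(cfg)
        ds, _ = clean_traces(ds)
        mean_abs_r = np.abs(correlation_matrix(ds).upper_weights()).mean()
        assert mean_abs_r < 3.0 / np.sqrt(ds.n_frames)

    def test_within_correlation_monotone_in_participation(self):
        means = []
        for participation in (0.3, 0.6, 0.9):
            vals = []
            for seed in range(3):
                cfg = SimulationConfig(
                    n_rois=40, n_assemblies=2, assembly_sizes=(20, 20),
                    burst_participation=participation, duration=600.0, seed=seed)
                ds, gt = simulate_larva(cfg)
                ds, _ = clean_traces(ds)
                net = correlation_matrix(ds)
                iu = np.triu_indices(net.n, 1)
                same = gt.assembly_label[iu[0]] == gt.assembly_label[iu[1]]
                vals.append(net.weights[iu][same].mean())
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestGroups:
    def test_group_contract(self):
        cfg = small_config()
        group = simulate_group(cfg, 8, regime="baseline", base_seed=100)
        assert len(group) == 8
        traces = [ds.traces for ds, _ in group]
        for i in range(1, 8):
            assert not np.array_equal(traces[0], traces[i])
        assert all(ds.meta["genotype"] == "baseline" for ds, _ in group)

    def test_shift_applied(self):
        cfg = small_config(burst_participation=0.7)
        shifted = shifted_config(cfg, participation_delta=0.2)
        assert shifted.burst_participation == pytest.approx(0.9)

    def test_shift_out_of_bounds_rejected(self):
        cfg = small_config(burst_participation=0.9)
        with pytest.raises(SimulationConfigError, match="participation"):
            simulate_group(cfg, 2, regime="shifted",
                           shift_params={"participation_delta": 0.3})

    def test_too_few_larvae_rejected(self):
        with pytest.raises(SimulationConfigError, match="n_larvae"):
            simulate_group(small_config(), 1)

    def test_unknown_regime_rejected(self):
        with pytest.raises(SimulationConfigError, match="regime"):
            simulate_group(small_config(), 2, regime="mutant")
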