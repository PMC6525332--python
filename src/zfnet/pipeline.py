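"""End-to-end orchestration: simulate → analyze → compare → map.

A run is driven by a declarative :class:`RunConfig` (YAML on disk).  All
randomness flows from the single ``seed``: per-larva simulation seeds and
per-larva surrogate seeds are derived from it deterministically, so a
rerun with the same configuration reproduces every numeric table
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datasets import GroupManifest, read_dataset, write_dataset
from .model import FunctionalNetwork
from .network import DEFAULT_DENSITY_GRID, DEFAULT_TAU_GRID
from .simulate import SimulationConfig, simulate_group
from .stats import anova_tukey, group_average, ks_compare, per_threshold_ttest
from .surrogates import SurrogateSpec

log = logging.getLogger("zfnet")

CSV_FLOAT = "%.12g"


@dataclass
class RunConfig:
    """Declarative configuration of one analysis run."""

    seed: int = 0
    trim_seconds: float = 60.0
    tau_grid: tuple = tuple(DEFAULT_TAU_GRID)
    density_grid: tuple = tuple(DEFAULT_DENSITY_GRID)
    surrogate_method: str = "circular_shift"
    n_surrogates: int = 100
    stat_alpha: float = 0.05
    stat_equal_var: bool = True
    stat_correction: str | None = None
    map_tau: float = 0.7
    map_window: float = 20.0
    map_stride: float = 5.0
    simulation: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: data[k] for k in cls.__dataclass_fields__ if k in data}
        cfg = cls(**known)
        for k in ("tau_grid", "density_grid"):
            setattr(cfg, k, tuple(float(v) for v in getattr(cfg, k)))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def surrogate_spec(self, larva_index: int = 0) -> SurrogateSpec:
        # per-larva surrogate seed streams, disjoint for n_surrogates <= 10^4
        return SurrogateSpec(
            method=self.surrogate_method,
            n_surrogates=self.n_surrogates,
            seed=int(self.seed + 10_000 * (larva_index + 1)),
        )


def run_simulate(config: RunConfig, out_dir: str | Path) -> Path:
    """Simulate the configured groups and write datasets plus a manifest.

    ``config.simulation`` holds the base :class:`SimulationConfig` fields
    under ``base`` and a list of groups, e.g.::

        simulation:
          base: {n_rois: 100, duration: 900}
          groups:
            - {regime: baseline, n_larvae: 8, age_dpf: 6}
            - {regime: shifted, n_larvae: 8, age_dpf: 6,
               shift_params: {participation_delta: 0.2}}
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation or {}
    base = SimulationConfig(**sim.get("base", {}))
    groups = sim.get("groups") or [{"regime": "baseline", "n_larvae": 2}]
    entries = []
    for g_idx, grp in enumerate(groups):
        regime = grp.get("regime", "baseline")
        n_larvae = int(grp.get("n_larvae", 2))
        results = simulate_group(
            base, n_larvae, regime=regime,
            shift_params=grp.get("shift_params"),
            base_seed=int(config.seed + 1000 * g_idx),
        )
        for ds, truth in results:
            ds.meta["age_dpf"] = int(grp.get("age_dpf", 0))
            name = f"{regime}_{g_idx}_{ds.meta['larva_id']}"
            ds.meta["larva_id"] = name
            path = out_dir / name
            write_dataset(ds, path)
            truth.to_json(path / "ground_truth.json")
            entries.append({
                "path": name, "age_dpf": ds.meta["age_dpf"], "genotype": regime,
            })
            log.info("simulated %s (%d ROIs x %d frames)", name,
                     ds.n_rois, ds.n_frames)
    manifest = GroupManifest(entries=entries)
    manifest.write(out_dir / "manifest.json")
    return out_dir / "manifest.json"


def _fit_all(manifest: GroupManifest, base: Path, config: RunConfig):
    """Fit every dataset in the manifest; returns list of
    (entry, FunctionalNetworkResults)."""
    fitted = []
    for idx, entry in enumerate(manifest.entries):
        t0 = time.perf_counter()
        ds = read_dataset(base / entry["path"])
        model = FunctionalNetwork(
            ds, tau_grid=np.asarray(config.tau_grid),
            density_grid=np.asarray(config.density_grid),
            trim_seconds=config.trim_seconds,
        )
        res = model.fit(surrogates=config.surrogate_spec(idx))
        fitted.append((entry, res))
        log.info("analyzed %s in %.1f s", entry["path"], time.perf_counter() - t0)
    return fitted


def run_analyze(
    manifest_path: str | Path,
    out_dir: str | Path,
    config: RunConfig,
) -> Path:
    """Analyze every dataset of a manifest and write all result tables.

    Outputs per larva: metrics, normalized metrics, density curve and
    edge-weight CDF as tidy CSVs; per group: pointwise mean ± SEM curves;
    plus a run manifest recording configuration, seeds and config hash.
    """
    manifest_path = Path(manifest_path)
    manifest = GroupManifest.read(manifest_path)
    base = manifest_path.parent
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    fitted = _fit_all(manifest, base, config)

    per_larva = []
    cdf_rows = []
    for entry, res in fitted:
        lid = entry["path"]
        frame = res.normalized.to_frame()
        frame.insert(1, "age_dpf", entry["age_dpf"])
        frame.insert(2, "genotype", entry["genotype"])
        frame["larva_id"] = lid
        per_larva.append(frame)
        mrows = res.metrics.reset_index()
        mrows.insert(0, "larva_id", lid)
        for _, row in mrows.iterrows():
            per_larva.append(pd.DataFrame([{
                "larva_id": lid, "age_dpf": entry["age_dpf"],
                "genotype": entry["genotype"], "tau": row["tau"],
                "metric": "r", "value": row["r"],
                "n_surrogates_used": 0,
                "method": config.surrogate_method, "seed": config.seed,
            }]))
        c = res.edge_cdf.to_frame()
        c.insert(0, "larva_id", lid)
        c.insert(1, "genotype", entry["genotype"])
        c.insert(2, "age_dpf", entry["age_dpf"])
        cdf_rows.append(c)
        dens = res.density.to_frame()
        dens.insert(1, "genotype", entry["genotype"])
        dens.insert(2, "age_dpf", entry["age_dpf"])
        cdf_rows.append(dens.rename(columns={"tau": "bin_right_edge",
                                             "value": "cumulative"})
                        .assign(metric="density"))

    metrics_table = pd.concat(per_larva, ignore_index=True)
    metrics_table.to_csv(out_dir / "metrics.csv", index=False,
                         float_format=CSV_FLOAT)
    pd.concat(cdf_rows, ignore_index=True).to_csv(
        out_dir / "distributions.csv", index=False, float_format=CSV_FLOAT)

    # group mean ± SEM per metric and τ
    summaries = []
    for (age, geno), sub in metrics_table.groupby(["age_dpf", "genotype"]):
        for metric, msub in sub.groupby("metric"):
            pivot = msub.pivot_table(index="larva_id", columns="tau",
                                     values="value", dropna=False)
            grid = pivot.columns.to_numpy(float)
            mat = pivot.to_numpy(float)
            defined = np.isfinite(mat)
            n = defined.sum(axis=0)
            filled = np.where(defined, mat, 0.0)
            mean = np.where(n >= 1, filled.sum(axis=0) / np.maximum(n, 1), np.nan)
            dev2 = np.where(defined,
                            (mat - np.where(n >= 1, mean, 0.0)[None, :]) ** 2, 0.0)
            sd = np.where(n >= 2, np.sqrt(dev2.sum(axis=0) / np.maximum(n - 1, 1)),
                          np.nan)
            summaries.append(pd.DataFrame({
                "age_dpf": age, "genotype": geno, "metric": metric,
                "tau": grid, "mean": mean,
                "sem": np.where(n >= 2, sd / np.sqrt(np.maximum(n, 1)), np.nan),
                "n": n,
            }))
    pd.concat(summaries, ignore_index=True).to_csv(
        out_dir / "group_summaries.csv", index=False, float_format=CSV_FLOAT)

    run_manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "n_datasets": len(fitted),
        "surrogate_seeds": [config.surrogate_spec(i).seed
                            for i in range(len(fitted))],
    }
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=2, sort_keys=True)
    return out_dir


def run_compare(
    manifest_path: str | Path,
    analyze_dir: str | Path,
    out_dir: str | Path,
    config: RunConfig,
    metrics: tuple = ("cl_norm", "l_norm", "t_norm", "sigma", "density"),
) -> Path:
    """Between-genotype and across-age comparisons from analyzed tables.

    For each age with two genotypes: per-threshold t tests on the graph
    metrics and a KS test on pooled pairwise correlations.  For each
    genotype spanning several ages: one-way ANOVA (+ Tukey HSD when
    significant) per metric and threshold.
    """
    manifest_path = Path(manifest_path)
    manifest = GroupManifest.read(manifest_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(Path(analyze_dir) / "metrics.csv")

    def curves_for(age, geno, metric):
        sub = table[(table.age_dpf == age) & (table.genotype == geno)
                    & (table.metric == metric)]
        out = []
        from .network import MetricCurve
        for lid, lsub in sub.groupby("larva_id"):
            lsub = lsub.sort_values("tau")
            out.append(MetricCurve(grid=lsub["tau"].to_numpy(),
                                   values=lsub["value"].to_numpy(),
                                   metric=metric, larva_id=str(lid)))
        return out

    rows = []
    ages = sorted({e["age_dpf"] for e in manifest.entries})
    genos = sorted({e["genotype"] for e in manifest.entries})
    for age in ages:
        here = [g for g in genos if manifest.paths_for(age, g)]
        if len(here) == 2:
            ga, gb = here
            for metric in metrics:
                ca, cb = curves_for(age, ga, metric), curves_for(age, gb, metric)
                if not ca or not cb:
                    continue
                res = per_threshold_ttest(
                    ca, cb, equal_var=config.stat_equal_var,
                    alpha=config.stat_alpha, correction=config.stat_correction)
                t = res.table.assign(test="t_test", metric=metric,
                                     age_dpf=age, group_a=ga, group_b=gb)
                rows.append(t)
            pool_a = manifest.load_group(age, ga, base=manifest_path.parent)
            pool_b = manifest.load_group(age, gb, base=manifest_path.parent)
            ks = ks_compare(pool_a, pool_b, alpha=config.stat_alpha)
            rows.append(ks.table.assign(test="ks", metric="edge_weights",
                                        age_dpf=age, group_a=ga, group_b=gb,
                                        tau=np.nan))
    for geno in genos:
        geno_ages = [a for a in ages if manifest.paths_for(a, geno)]
        if len(geno_ages) >= 2:
            for metric in metrics:
                for tau in config.tau_grid:
                    groups = {}
                    for a in geno_ages:
                        vals = table[(table.age_dpf == a)
                                     & (table.genotype == geno)
                                     & (table.metric == metric)
                                     & (np.isclose(table.tau, tau))]["value"]
                        vals = vals[np.isfinite(vals)]
                        if len(vals) >= 2:
                            groups[a] = vals.to_numpy()
                    if len(groups) >= 2:
                        res = anova_tukey(groups, alpha=config.stat_alpha)
                        rows.append(res.table.assign(
                            test="anova", metric=metric, tau=tau,
                            age_dpf=np.nan, group_a=geno, group_b=""))
    if rows:
        pd.concat(rows, ignore_index=True).to_csv(
            out_dir / "comparisons.csv", index=False, float_format=CSV_FLOAT)
    return out_dir


def run_map(
    manifest_path: str | Path,
    larva: str,
    out_dir: str | Path,
    config: RunConfig,
    metric: str = "clustering",
) -> Path:
    """Spatial map of a node metric for one larva at the map threshold."""
    manifest_path = Path(manifest_path)
    manifest = GroupManifest.read(manifest_path)
    entry = next((e for e in manifest.entries if e["path"] == larva), None)
    if entry is None:
        raise FileNotFoundError(f"larva {larva!r} not in manifest")
    ds = read_dataset(manifest_path.parent / entry["path"])
    idx = manifest.entries.index(entry)
    model = FunctionalNetwork(
        ds, tau_grid=np.asarray(config.tau_grid),
        density_grid=np.asarray(config.density_grid),
        trim_seconds=config.trim_seconds,
    )
    res = model.fit(surrogates=config.surrogate_spec(idx))
    smap = res.spatial_map(metric=metric, tau=config.map_tau,
                           window_size=config.map_window,
                           stride=config.map_stride)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    smap.to_frame().to_csv(out_dir / f"map_{larva}_{metric}.csv",
                           index=False, float_format=CSV_FLOAT)
    try:
        import matplotlib
        matplotlib.use("Agg")
        ax = res.plot_map(metric=metric, tau=config.map_tau,
                          window_size=config.map_window,
                          stride=config.map_stride)
        ax.figure.savefig(out_dir / f"map_{larva}_{metric}.png", dpi=150)
    except Exception as exc:  # rendering is best-effort; the CSV is canonical
        log.warning("map rendering failed: %s", exc)
    return out_dir
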