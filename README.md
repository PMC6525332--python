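# zfnet — functional-network analysis of larval zebrafish calcium imaging

`zfnet` turns resting-state calcium-imaging recordings of larval zebrafish —
per-neuron ΔF/F traces extracted from multiplane two-photon movies — into
thresholded binary correlation networks and quantifies their topology with
surrogate-normalized graph measures.  It is written for systems
neuroscientists comparing functional network organization across
developmental ages or genotypes (e.g. wild-type vs mutant groups of 8–11
larvae), and ships a synthetic multiplane calcium-data generator so every
stage of the pipeline can be exercised and validated without real imaging
data.

## The analysis

Nodes are segmented ROIs (putative neurons); the edge weight between nodes
*i* and *j* is the Pearson correlation of their ΔF/F traces.  After
discarding the first minute of each recording, the pipeline computes per
larva:

* the **cumulative edge-weight distribution** (50 bins on [−1, 1]) and the
  **network density** `edges / (n(n−1)/2)` over a threshold grid;
* binary undirected networks at each global threshold τ (edge kept iff
  weight > τ), and on them the four standard measures
  * mean clustering coefficient `Cl = (1/N) Σ 2tᵢ / (kᵢ(kᵢ−1))`,
  * characteristic path length `L` (mean shortest path over reachable
    pairs),
  * transitivity `T = Σ2tᵢ / Σkᵢ(kᵢ−1)`,
  * degree assortativity `r` (correlation of end-node degrees over edges);
* **surrogate-normalized** versions: each trace is independently
  circularly shifted (or Fourier phase-randomized) to destroy cross-trace
  alignment while preserving its marginal distribution and
  autocorrelation; each of the (default 100) surrogate networks is
  thresholded at its own τ′ matching the experimental network's density;
  `Cl_norm = Cl / Cl_rand`, `L_norm = L / L_rand`, `T_norm = T / T_rand`
  and small-worldness `σ = Cl_norm / L_norm` (σ > 1 ⇒ small-world
  organization);
* group statistics: mean ± SEM curves per (age, genotype) group, unpaired
  two-tailed Student's t tests per threshold, one-way ANOVA with Tukey HSD
  across ages, and Kolmogorov–Smirnov tests on pairwise correlations
  pooled across the larvae of each group;
* **spatial maps**: node metrics (normalized clustering, max-normalized
  degree) averaged in sliding 20 × 20 μm windows over ROI positions.

Undefined values (metrics of empty or degenerate graphs) propagate as
missing and are excluded from ensemble and group means with recorded
counts — never coerced to zero.

## Worked example

```python
from zfnet import SimulationConfig, simulate_larva, FunctionalNetwork, SurrogateSpec

config = SimulationConfig(n_rois=100, n_assemblies=5, assembly_sizes=(20,) * 5,
                          duration=900.0, burst_participation=0.8, seed=7)
dataset, truth = simulate_larva(config)   # 100 ROIs x 900 frames at 1 Hz

model = FunctionalNetwork(dataset, tau_grid=[0.0, 0.1, 0.2, 0.3, 0.4],
                          trim_seconds=60.0)
results = model.fit(surrogates=SurrogateSpec(n_surrogates=25, seed=1))
print(results.summary())
```

```
           Functional network: sim7 | 100 ROIs x 840 frames
======================================================================
tau  density   Cl     L      T       r    Cl_norm L_norm T_norm sigma
----------------------------------------------------------------------
0.00  0.5570 0.6745 1.4430 0.6666  0.0806  1.1692 1.0000 1.1560 1.1692
0.10  0.2606 0.7504 1.9800 0.7143  0.2398  2.3926 1.1372 2.2787 2.1040
0.20  0.1909 0.9374 2.3420 0.9310  0.0047  3.7332 1.2709 3.7098 2.9373
0.30  0.1378 0.8265 1.2832 0.8181  0.1207  4.0231 0.6332 4.0003 6.3539
0.40  0.0382 0.3704 1.9074 0.4347 -0.1312  3.9770 0.5237 3.9911 7.5934
----------------------------------------------------------------------
```

This larva carries five planted assemblies of 20 neurons firing
synchronous bursts.  Density falls as the threshold rises; normalized
clustering climbs to ≈ 4 — the assemblies survive thresholding as tightly
clustered cliques while density-matched surrogates scatter the same number
of edges — and σ > 1 across the grid signals small-world organization.  On
unstructured data all normalized columns sit at ≈ 1.

`results.spatial_map("degree_norm", tau=0.3)` returns the sliding-window
map of max-normalized degree; `results.plot_metrics()` and
`results.plot_map()` render the curves and maps.

## Command line

```bash
zfnet simulate --config run.yaml --out data/        # grouped synthetic larvae + manifest
zfnet analyze  --manifest data/manifest.json --config run.yaml --out tables/
zfnet compare  --manifest data/manifest.json --analyzed tables/ --out stats/
zfnet map      --manifest data/manifest.json --larva baseline_0_baseline_00 \
               --tau 0.7 --out maps/
```

All numeric tables are tidy CSVs carrying the seeds and config hash that
produced them; a rerun with the same configuration reproduces them
byte-for-byte.

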