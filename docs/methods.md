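# Methods

## Scope and model of the data

`zfnet` analyzes resting-state functional connectivity in larval zebrafish
from segmented calcium-imaging output: one ΔF/F trace per ROI (putative
neuron), ROI coordinates (x, y in μm, imaging plane, z), a fixed frame
interval, and per-larva metadata (age in dpf, genotype).  It deliberately
starts *after* segmentation — acquisition and CNMF-style trace extraction
are upstream concerns — and treats the trace matrix as the primary object.
Functional connectivity is defined as zero-lag Pearson correlation; no
lagged or partial correlation is modeled.

Preprocessing applies two rules before any correlation is computed:

* **Initial trim** (default 60 s): scanning onset produces a transient
  fluorescence artifact, so the first minute is removed uniformly from
  every recording.  The trim is specified in seconds
  (`floor(trim_seconds / frame_interval)` frames) so it is robust to
  frame-rate changes.
* **Degenerate-ROI removal**: traces with zero variance or non-finite
  entries make the Pearson coefficient undefined and are dropped (with
  their IDs reported), not assigned r = 0.

## Network construction

The correlation matrix uses the sample Pearson coefficient per unordered
pair, diagonal fixed at 0, explicitly symmetrized (BLAS matrix products
are not bitwise symmetric) and clipped to [−1, 1] against rounding.
Edge-weight distributions are cumulative over 50 equal-width bins on
[−1, 1], right-edge inclusive, so the final value is exactly 1.

Binarization keeps an edge iff weight > τ (strict).  Strictness is a
deliberate tie-break: at τ = 0 exactly-zero correlations are excluded,
negative weights never survive τ ≥ 0, and results are reproducible to the
bit.  Ties at a threshold have measure zero on real-valued data.  The
default grid for the complex metrics is τ ∈ {0.0, …, 0.7} (step 0.1);
density curves extend to 0.9.  Both are configurable.

## Graph measures

Degree, per-node triangle counts (t_i = (A³)_ii / 2), clustering
(c_i = 2t_i / (k_i(k_i−1)), c_i = 0 when k_i < 2, network value = mean
over all nodes), characteristic path length (unweighted BFS distances,
mean over ordered pairs with finite distance, unreachable-pair count
reported), transitivity (Σ2t_i / Σk_i(k_i−1)) and degree assortativity
(the edge-list correlation formula, each undirected edge counted once with
degrees entering symmetrically) are implemented directly from their
binary-undirected definitions and validated two ways: against naive
brute-force oracles (triple enumeration, Floyd–Warshall, direct edge-list
sums in `zfnet.oracles`) and against networkx, on hundreds of seeded random
graphs, to 1e−12.

Degenerate values are first-class: L on an edgeless graph, T without a
connected triple, and r on a regular graph (zero degree variance) are NaN,
propagate as missing, and are excluded from ensemble/group means with
recorded counts.  Disconnected graphs are routine at high thresholds, so
L averages finite distances only; an efficiency-based variant was
considered and rejected as a default because the finite-pair mean is the
convention established for this analysis style.

## Surrogate normalization

Raw graph measures depend strongly on density, so each measure is
normalized by a null ensemble built from the *same data*: every trace is
independently randomized in time, correlations recomputed, and the
surrogate network thresholded at its own τ′ chosen to reproduce the
experimental network's density at τ.

* **Randomization**: the default is an independent circular shift per
  trace (offset uniform on 1..n_frames−1) — a permutation, so each
  trace's marginal distribution and autocorrelation are preserved exactly
  while cross-trace alignment is destroyed.  Fourier phase randomization
  (amplitude spectrum preserved) is available as an option.  The method
  and seed are recorded in every output.
* **Density matching** is per surrogate, not on the ensemble average:
  with k = round(density × n_pairs), τ′ is the midpoint between the k-th
  and (k+1)-th largest surrogate weights, so exactly k edges survive
  (boundary ties resolve toward fewer edges).  The achieved density is
  asserted — not assumed — to be within 0.5/n_pairs of the target for
  every surrogate at every threshold.
* **Ensembles**: 100 surrogates by default (surrogate i uses seed + i);
  Cl, L and T share one ensemble per dataset so the normalized metrics
  are mutually consistent.  A τ cell of an ensemble mean is reported
  missing when more than half the surrogates are undefined there.

Cl_norm = Cl/Cl_rand, L_norm = L/L_rand, T_norm = T/T_rand, and
small-worldness σ = Cl_norm/L_norm, with σ > 1 read as small-world
organization.  On i.i.d. Gaussian traces (60 ROIs × 600 frames, 25
surrogates) the ensemble means of all four ratios measure 1.00 ± 0.02 at
thresholds inside the null edge-weight support (τ ≤ ~0.05; the null
Pearson spread is ≈ 1/√n_frames ≈ 0.04).  Above that support the networks
are empty and the ratios are correctly reported missing — a normalized
metric at a threshold outside the data's weight support is meaningless,
not 1.

## Group statistics

Curves are averaged pointwise within (age, genotype) groups as mean ± SEM
(sample sd / √n, missing cells excluded with per-cell n).  Comparisons
follow the conventions of this analysis style:

* unpaired two-tailed Student's (pooled-variance) t test per threshold;
  Welch available by flag; no correction across thresholds by default
  (a Bonferroni option exists) and the number of tests performed is
  always recorded;
* one-way ANOVA across ages with Tukey HSD pairwise tests computed only
  when the ANOVA is significant;
* two-sample KS on pairwise correlation coefficients pooled across all
  larvae of a group (the pooled-pair convention — per-group n is the
  total pair count, which reaches millions on real multiplane data); a
  per-larva-distribution alternative is available via
  `pool_edge_weights` on individual datasets.

## Spatial maps

Node metrics are averaged in sliding windows (default 20 × 20 μm, 5 μm
stride) over ROI (x, y) positions with planes collapsed; per-plane maps
are an option.  Window origins sit on the absolute stride grid (multiples
of the stride), so translating all coordinates by one stride shifts the
map by exactly one cell.  Membership is lower-edge inclusive, upper-edge
exclusive; empty windows are masked undefined and every defined cell
equals the exact mean over its member ROIs.  Degree maps are normalized
to each network's maximum degree (values in (0, 1]); clustering maps are
divided by the surrogate-ensemble mean clustering when normalized results
are available.  Default map threshold τ = 0.7; maps are per larva.

## Synthetic data generator

The generator emulates what resting-state recordings of 3–6 dpf larvae
look like after segmentation: hundreds of ROIs sampled for ~15 min at
1 frame/s, mostly quiet, with assembly-wide synchronous bursts riding on
sparse background transients, rendered through a slow indicator.

The forward model, per larva (all randomness from one seed):

1. ROI positions uniform in the field (default 500 × 500 μm), planes
   assigned round-robin (default 12 planes, 10 μm spacing).
2. Background spikes per ROI: homogeneous Poisson (default 0.04 s⁻¹).
3. Per assembly (default 5 assemblies of 20 ROIs in 100), burst events as
   Poisson (default 0.05 s⁻¹); each member joins each event independently
   with probability `burst_participation` (default 0.8).
4. Spikes are binned to the frame grid and convolved with the causal
   kernel exp(−t/τ_decay), τ_decay = 3.5 s (slow GCaMP6s-like decay at
   1 Hz sampling), implemented as a first-order recursive filter; spike
   amplitudes are jittered with CV 0.3 (clipped at 0).
5. i.i.d. Gaussian read noise, sd 0.05 ΔF/F; per-trace baseline 0.

Rates and amplitudes are calibration choices — no firing statistics are
published for these recordings — picked so that within-assembly
correlations land around 0.3–0.45 and between-assembly correlations at 0,
which reproduces the qualitative regime (synchronous bursts, heavy right
tail of edge weights, small-world topology after thresholding).  Group
simulations apply a regime label: "shifted" adds `participation_delta`
and/or `rate_delta` to the baseline configuration (validated against
[0, 1]), larva i uses seed base_seed + i, and the regime is recorded as
the genotype.

What the generator does *not* emulate: anatomy (positions are uniform, so
spatial-map tests use planted gradients instead), movies and segmentation
artifacts, motion, indicator nonlinearity and saturation, inhibition or
negative coupling, and slow nonstationarities.  Passing tests therefore
demonstrate the pipeline's correctness and sensitivity under a known
forward model, not performance on real recordings.

## Validation experiments and their problem sizes

The acceptance experiments (`zfnet.experiments`, driven by
`scripts/acceptance.py` and `tests/test_acceptance.py`) run at desk scale,
chosen so the full suite completes in minutes on one CPU:

* oracle check: 200 random graphs, n ≤ 12;
* null calibration: 20 noise datasets of 60 ROIs × 600 frames, 25
  surrogates (scaled down from the default 100);
* small-world recovery: 10 replicates of a structured larva (5 assemblies
  of 20, participation 0.8, 900 s) against a matched control, 20
  surrogates;
* group contrast: 10 replicate experiments of 8 + 8 larvae
  (participation 0.7 vs 0.9), 20 surrogates.

Two operationalizations deserve note.  A τ cell enters the small-world
comparison only when the network is super-critical (mean degree ≥ 1,
density ≥ 1/(n−1)): below the giant-component threshold a graph is
fragmented dust and ratio metrics are dominated by a handful of edges.
And the matched unstructured control is the circular-shift randomization
of the same larva evaluated at *matched density* via its own τ′ — no
unstructured dataset has edge weights above ~0.33 at these recording
lengths, so a same-τ comparison at τ ≥ 0.3 would compare against empty
graphs.  Under these definitions structured larvae show σ ≈ 5–9 and
Cl_norm ≈ 4 against control Cl_norm ≈ 1.

A planted participation shift moves the pooled edge-weight distribution
(KS detects it essentially always) and the density curves, but is largely
cancelled in Cl_norm by the density-matched normalization — normalized
clustering measures assembly *structure*, which both regimes share — so
Cl_norm t-test detection is weaker than KS detection.  This is a property
of the statistic, not a defect of the test.

## Numerical choices

* All randomness flows through `numpy.random.default_rng` from explicit
  seeds; derived seeds are simple offsets so streams are disjoint and
  reproducible.  Identical configuration + seed reproduces every numeric
  table byte-for-byte (CSV floats written at fixed precision, read back
  with round-trip parsing).
* Dataset files are plain text (CSV + JSON) for inspectability; ground
  truth is a JSON sidecar.
* Thresholding uses strict inequality everywhere (see above); matched
  thresholds break ties toward fewer edges.
* Metrics near machine precision are compared at 1e−12 in tests; the
  triangle count rounds (A³)_ii/2 to the nearest integer to absorb
  float error from the matrix product.

## Known limitations

* Zero-lag Pearson correlation misses lagged or nonlinear coupling.
* The finite-pair mean for L makes values at very high thresholds
  incomparable across networks with different fragmentation; the
  unreachable-pair count is reported for that reason.
* The per-trace circular shift preserves circular, not linear,
  autocorrelation; for strongly nonstationary traces phase randomization
  may be preferable.
* Group KS on pooled pairs treats pairs as exchangeable across larvae;
  with few larvae the effective sample size is far below the pooled pair
  count, so its p-values should be read as descriptive, as is
  conventional for this comparison.
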