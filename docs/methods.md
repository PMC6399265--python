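# Methods

This note documents the models and procedures implemented in `connhier`,
the choices made where the design was genuinely open, and what the
synthetic cohorts can and cannot establish about real data.

## The synthetic cohort model

Each cohort lives on a `NodeSpace` of `n` parcels (default 200) divided
into seven functional communities mapped to four hierarchy levels
(1 visual + somatomotor, 2 dorsal attention + salience, 3 frontoparietal,
4 DMN + limbic; the DMN is the largest community, as in real
parcellations). Every node carries a hierarchy score `h ∈ [0, 1]` drawn
around its community's center; the centers are spread with near-uniform
gaps (≤ 0.15) and within-community jitter SD 0.08 so the
unimodal→transmodal axis is continuous — a discrete, gappy axis would
disconnect the thresholded affinity graph, which real cortical gradients
never are. Spatially, community centroids follow a concave map
`x = 140·√h` with cluster scatter shrinking toward the apex: primary
cortices are mutually distant and internally dispersed, the transmodal apex
compact. Euclidean distances on these coordinates stand in for cortical
geodesics; only the qualitative distance–hierarchy coupling is preserved.

A subject's weight matrix is

```
w_ij = exp(−|h'_i − h'_j| / τ_h) + β_c·[c_i = c_j]
       + s_hub·(h'_i² + h'_j²)/2 + ε_ij,     h' = 0.5 + γ·(h − 0.5)
```

followed by `(1 − ρ)` multiplication of pairs farther apart than `d0`, a
site-specific global scale and offset, motion-proportional noise,
symmetrization and a zero diagonal. Defaults: `τ_h = 0.30` (hierarchy decay
length), `β_c = 0.10` (community bonus, deliberately secondary to the
hierarchy term), `s_hub = 1.2`, `d0 = 35` length units, weight noise
SD 0.06. The hub term makes apex nodes enter even distant rows' strongest
connections — the network-wide, long-range connectivity of empirical
rich-club hubs — and is the structural carrier of both planted effects:
compression (`γ < 1`) shrinks `h'` and with it the hub term
(quadratically), and attenuation (`ρ`) weakens exactly the long hub edges.
These structural defaults were calibrated once against the generator's
qualitative targets (recoverable hierarchy, transmodal rich club, sensory
long-range profile) and then frozen.

Group effect sizes default to `γ = 0.7`, `ρ = 0.3` for cases (controls
1.0 / 0.0) with between-subject SD 0.10 — cases span roughly `γ ∈
[0.5, 0.9]`, modelling severity heterogeneity. Symptom scores exist for
cases only (as with ADOS): `score = intercept + Σ βᵢ·fᵢ + noise` on the
planted per-subject summaries `(1 − γ, ρ)`, rounded and floored at 0, with
the noise SD derived from the linear predictor's variance so the
generating model's population R² is 0.5 (recorded, with the achieved
sample R², in provenance). Per-subject random streams are keyed by
`(master_seed, site, group, index-within-cell)`, so enlarging a cohort
never changes existing subjects.

Optionally, zero-mean multivariate-normal time series are sampled whose
correlation target is the unit-diagonal-rescaled weight matrix, PSD-repaired
by diagonal loading to a minimum eigenvalue of 1e−6 and re-normalized.

What the generator does **not** emulate: fMRI acquisition physics, temporal
autocorrelation, mesh geodesics, hemispheres, spatially structured noise,
or a DMN that is itself spatially distributed. Passing tests therefore show
the pipeline's statistics behave correctly under a faithful planted model,
not that any particular empirical effect exists.

## Gradients

Affinity construction follows the standard gradient-mapping chain: per-row
top-density thresholding (ties broken toward lower node indices so exactly
`⌈density·(n−1)⌉` entries survive; retained weights unmodified), cosine
similarity between thresholded rows with negatives clipped to 0 and unit
diagonal. Fisher-z transforms clip `r = ±1` to `±(1 − 1e−7)`.

The diffusion embedding solves the α-normalized operator through its
symmetric conjugate (`D^{-1/2} W' D^{-1/2}`), which makes the spectrum real
and the trivial constant eigenvector exactly identifiable; eigenvectors are
normalized in the stationary measure (the convention of the reference
diffusion-map lineage). At diffusion time `t = 0` (the default) component
`i` is scaled by the multiscale factor `λᵢ/(1−λᵢ)`; `t > 0` uses `λᵢ^t`.
A uniform affinity yields an exactly zero non-trivial spectrum and sets a
degenerate flag. Variance explained is `λᵢ/Σλ` over the computed
non-trivial spectrum — the normalization is recorded because other
conventions (e.g. including unreturned components) give different numbers.

Alignment is orthogonal Procrustes after column centering — rotation and
reflection only, no scaling — to a template embedded from the pooled
group-average connectome, with the template's component 1 oriented so
transmodal anchors score above unimodal anchors. Aligned scores are
returned in template space (template column means added back), so identical
inputs align to the template exactly. Ten components are computed and all
are used for alignment by default.

## Stepwise functional connectivity

SFC degree at step `l` is the walk count `(A^l e_seeds)_i` on the
binarized, union-symmetrized thresholded matrix. The iteration renormalizes
the count vector to unit maximum each step (logged for audit); since
z-standardization is invariant to positive scaling, the resulting z-maps
equal those from exact arbitrary-precision integer counts (verified to
1e−10 in the tests). Steps with zero across-node variance are stored as
missing and flagged.

Open details fixed here: "reaching" a level means the level's mean first
step at which a node's z-map exceeds `θ = 1` z, censored at the horizon `L`
(default 200); group-guided individual maps multiply the group and subject
maps elementwise after min–max rescaling each step's map to `[0, 1]` (raw
products of z-maps would make signs meaningless), then re-standardize; the
four per-level prediction features average each subject's z-maps over the
contiguous step window in which the control-template level mean is above
`θ` and contains its peak (falling back to the peak step alone when the
level never crosses `θ`).

## Rich club, distance

`φ(k)` is computed for `k = 1..max degree`; binary mode is subgraph density
among nodes of degree > k, weighted mode (the default, matching a weighted
connectome analysis) divides the subgraph weight by the sum of the `E_{>k}`
strongest weights anywhere. Both are computed in one cumulative pass over
the degree-sorted node order. Nulls are degree-preserving double-edge swaps
(10 attempts per edge by default) with weights carried along edges; the
swap loop is JIT-compiled when numba is available, with a bit-identical
pure-Python fallback (both consume the same pre-drawn random streams).
`k'` maximizes `φ_norm` (smallest k on ties) on the pooled group-average
connectome — a single consensus taxonomy avoids group-specific node sets.
"10% of connections to rich nodes" is an edge-count fraction. Node
connectivity distance is the mean distance of a node's binarized
suprathreshold connections; the SFC distance trajectory averages it over
active nodes per step (unweighted by default; a z-weighted variant is
available).

## Group statistics

Per-node OLS with intercept, group indicator, and covariates (age and site
dummies by default; motion, sex, or mean connectivity optionally). `t` is
the group coefficient over its standard error; Cohen's d divides the
adjusted group difference by the residual SD. With no covariates this
reproduces the classical pooled two-sample t-test exactly. FDR is
Benjamini–Hochberg. The cluster test residualizes covariates on the full
sample, permutes group labels, thresholds |t| at the two-sided
cluster-defining α (default 0.01), takes connected components on a
k-nearest-neighbour (k = 6) coordinate graph, and compares observed cluster
sizes against the permutation distribution of the maximum size with the
`+1` p-value formula (never exactly zero). Because cluster sizes are small
integers, these p-values are discrete; calibration checks use the
randomized probability integral transform, which is exactly Uniform(0, 1)
under exchangeability.

## Prediction

Features are `(gradient 1, SFC level 1..4) × node`. Outer 5-fold splits are
stratified by score quintile and repeated (default 100 repetitions; smaller
desk-scale runs record their repetition count in provenance). Inside each
training split, a 4-fold rotation tunes the elastic-net penalty over a
20-point log grid from the data-derived `α_max` down to `10⁻³·α_max`
(l1 ratio 0.5) by validation MAE; features with nonzero coefficients at the
chosen penalty are selected; a linear-kernel SVR with `C ∈ {0.1, 1, 10}`,
`ε ∈ {0.01, 0.1}` is tuned the same way and fit on the selected features.
Covariate correction (age + site) is leakage-safe by default — coefficients
fit on training rows only — with a full-sample mode available. Performance
is the median (k-fold) or mean (leave-one-site-out) over repetitions of the
pooled out-of-fold Pearson r and MAE; significance is a label-permutation
test of the median r with the `+1` formula (each permutation re-runs the
full selection/tuning pipeline at a reduced repetition count, recorded in
provenance). Out-of-fold null r carries the usual small negative bias that
shrinks with n.

## Problem sizes

The shipped tests and the acceptance script run at single-workstation
sizes, chosen as the package's reference conditions: 200-node spaces,
50 cases / 50 controls across two sites, SFC horizons of 100–120 steps,
100 rewired nulls, 250–500 cluster permutations, 5 CV repetitions and
50 score permutations. The full-scale defaults (L = 200, 1000 nulls,
10000 cluster permutations, 100 repetitions, 1000 permutations) are the
`RunConfig` defaults and run unchanged, only longer.

## Known limitations

- All planted group effects reach the aligned gradient through the
  multiscale amplitude `λ₁/(1−λ₁)` rather than the eigenvector shape:
  γ-compression is a monotone transform of `h`, so per-row threshold ranks
  (and with them the unit eigenvector) barely change. At 5–10% density
  compression lowers the case λ₁ (affinity more uniform) and the planted
  contraction is detected; at 25% density attenuation of the abundant
  retained long-range edges *raises* the case λ₁ (modularization), and the
  gradient-contrast and distance-correlation directions invert. The
  robustness battery documents this honestly: those two directions are not
  preserved at 25% density under this generator.
- The transmodal hub term is necessarily aligned with the global signal, so
  global signal regression strips proportionally more hub connectivity from
  controls than cases; the steps-to-reach group direction flips under GSR
  (it persists at long time series, so it is structural, not sampling
  noise). Real DMN hubs are less rank-one than this construction.
- The generator's symptom model couples severity to the true per-subject
  `(γ, ρ)`; imaging-based prediction accuracy is therefore bounded by how
  well the features estimate those parameters, not by the planted R² alone.
- Euclidean distances understate the geodesic lengths of real cortex;
  external distance matrices can be supplied as drop-in files.
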