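# connhier

Functional connectome **hierarchy** analysis for case–control rs-fMRI
studies, exercised end-to-end on synthetic multi-site cohorts with a planted
cortical hierarchy.

Atypical cortical hierarchy is a leading systems-level account of autism:
the smooth macroscale axis running from primary sensory/motor cortex to the
transmodal default-mode network (DMN) appears compressed, and long-range
connections attenuated, in affected individuals. This package implements
the full analysis chain used to test that account on parcel-level
functional connectomes:

1. **Connectome construction** — Fisher-z Pearson correlation matrices from
   regional time series, per-row top-density thresholding (default top 10%),
   optional global signal regression.
2. **Connectome gradients** — cosine-affinity matrices embedded by
   diffusion maps. With affinity `A`, degrees `d_i = Σ_j a_ij` and
   anisotropy `α = 0.5`, the operator is the row-normalized Markov matrix of
   `W'_ij = a_ij / (d_i d_j)^α`; gradients are its non-trivial right
   eigenvectors scaled by `λ/(1−λ)`, Procrustes-aligned (rotation only, no
   scaling) to a group template. Component 1 is the principal
   unimodal→transmodal gradient.
3. **Stepwise functional connectivity (SFC)** — the number of walks of
   exact length `l` from sensory seeds (V1/A1/S1) to every node,
   z-standardized per step; per-level *steps-to-reach* statistics and
   group-guided individual maps.
4. **Rich club and connectivity distance** — `φ(k)` normalized against
   degree-preserving rewired nulls, `k'` = argmax `φ_norm`, rich/feeder/local
   taxonomy (feeder: ≥10% of edges to rich nodes), per-node mean connection
   distance and its correlation with group-difference t-maps.
5. **Group statistics** — per-node OLS with age/site covariates, BH-FDR,
   maximum-cluster-size permutation testing (covariates residualized before
   permuting), community z-scores versus controls, Cohen's d.
6. **Severity prediction** — elastic-net feature selection (l1 ratio 0.5)
   plus linear SVR over `5 × n_nodes` features (gradient 1 + four
   level-averaged SFC maps) in stratified nested 5-fold cross-validation,
   with label-permutation significance and leave-one-site-out evaluation.

The synthetic cohort generator (`connhier.cohort`) plants everything the
pipeline is supposed to find: seven functional communities on four
hierarchy levels, a smooth hierarchy score per node, distance-dependent
connectivity with transmodal hubs, two case-group effects — gradient
**compression** (`γ < 1`) and **long-range attenuation** (`ρ > 0`) — site,
age, sex and motion confounds, and symptom scores linearly coupled to each
subject's planted effect sizes.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
from connhier import CohortConfig, make_cohort, cohort_gradients

space, manifest, connectomes, _ = make_cohort(
    CohortConfig(n_per_group_per_site=8, master_seed=3))
grads, template = cohort_gradients(
    connectomes, density=0.10,
    transmodal_nodes=space.level_indices(4),
    unimodal_nodes=space.level_indices(1))

ve = 100 * template.eigenvalues / template.eigenvalues.sum()
print(np.round(ve[:3], 1))          # -> [16.2 15.5 14.6]
rho = np.median([spearmanr(g.gradient(1), space.hierarchy_score).statistic
                 for g in grads])
print(round(rho, 3))                # -> 0.998
```

The first line is the percentage of connectome variance explained by the
leading gradients of the group template; the second is the median Spearman
correlation between each subject's aligned principal gradient and the
planted hierarchy score — at these settings the embedding recovers the
planted axis almost perfectly. The scripts in `examples/` walk through each
capability the same way (simulation, gradients, SFC, rich club + distance,
group statistics, prediction, and the full pipeline runner).

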