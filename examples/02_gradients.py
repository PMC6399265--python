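"""Connectome gradients: threshold -> cosine affinity -> diffusion embedding
-> Procrustes alignment to the pooled template.

Prints the variance explained by the leading components and shows that the
principal gradient recovers the planted hierarchy ordering.
"""

import numpy as np
from scipy.stats import spearmanr

from connhier import CohortConfig, cohort_gradients, make_cohort

space, manifest, connectomes, _ = make_cohort(
    CohortConfig(n_per_group_per_site=8, master_seed=3))

grads, template = cohort_gradients(
    connectomes,
    density=0.10,            # top 10% of weighted connections per row
    n_components=10,
    transmodal_nodes=space.level_indices(4),
    unimodal_nodes=space.level_indices(1),
)

ve = 100 * template.eigenvalues / template.eigenvalues.sum()
print("variance explained by template components (%):", np.round(ve[:5], 1))
rhos = [spearmanr(g.gradient(1), space.hierarchy_score).statistic for g in grads]
print(f"Spearman(gradient 1, planted hierarchy): "
      f"median {np.median(rhos):.3f}, min {np.min(rhos):.3f}")
g1 = np.stack([g.gradient(1) for g in grads])
for lev in (1, 4):
    m = g1[:, space.level_indices(lev)].mean()
    print(f"  mean aligned gradient-1 score at level {lev}: {m:+.1f}")
# Component 1 runs from sensory (negative) to DMN (positive) by the template
# orientation convention; a |rho| near 1 means the embedding orders nodes
# exactly along the planted unimodal-to-transmodal axis.
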