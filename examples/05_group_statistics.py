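"""Node-level group inference on the principal gradient.

Covariate-adjusted linear models (age + site), BH-FDR across nodes, a
maximum-cluster-size permutation test, and community z-scores against the
control distribution.
"""

import numpy as np

from connhier import (
    CohortConfig, build_design, cohort_gradients, community_zscores,
    fit_node_models, knn_adjacency, make_cohort, permutation_cluster_test,
)

space, manifest, connectomes, _ = make_cohort(
    CohortConfig(n_per_group_per_site=12, master_seed=13))
grads, _ = cohort_gradients(connectomes,
                            transmodal_nodes=space.level_indices(4),
                            unimodal_nodes=space.level_indices(1))
g1 = np.stack([g.gradient(1) for g in grads])

X, names = build_design(manifest, covariates=("age", "site"))
res = fit_node_models(g1, X, design_names=names)
print(f"design columns: {names}")
print(f"nodes with q < 0.05: {res.significant.sum()} of {len(res.t)}")
lv4 = space.level_indices(4)
print(f"mean t at level 4 (DMN): {np.nanmean(res.t[lv4]):+.1f} "
      f"(negative = case reduction)")

clusters = permutation_cluster_test(
    g1, manifest, knn_adjacency(space.coordinates, k=6),
    covariates=("age", "site"), cdt=0.01, n_perm=1000, seed=13)
top = clusters.sort_values("size", ascending=False).head(3)
print(top[["cluster_id", "size", "p"]].to_string(index=False))

commz = community_zscores(g1, space.community, manifest["group"].to_numpy())
print(commz[["community", "z", "q", "significant"]].round(3).to_string(index=False))
# Community 7 is the DMN: its strongly negative z-score relative to controls
# is the community-level signature of the planted gradient compression.
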