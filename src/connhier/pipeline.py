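"""End-to-end pipeline: simulate -> connectome -> gradients -> SFC ->
rich club -> distance -> group statistics -> prediction.

`RunConfig` collects every stage's tunable with defaults at the analysis'
reference values (10% row density, alpha = 0.5, L = 200 SFC steps,
theta = 1 z activation, 1000 rewiring nulls, 10000 cluster permutations,
1000 prediction permutations). ``run_pipeline`` executes the stages in
dependency order, writes tidy TSV/JSON outputs with provenance, and returns
the in-memory results for programmatic use. Fixed seeds make the whole run
deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortConfig, make_cohort
from .connectome import (
    correlation_connectome, group_average, regress_global_signal,
    threshold_rows,
)
from .distance import (
    correlate_tmap_distance, distance_matrix, mean_connectivity_distance,
    sfc_distance_group_contrast, sfc_distance_trajectory,
)
from .gradients import cohort_gradients
from .groupstats import (
    build_design, community_zscores, fit_node_models, knn_adjacency,
    permutation_cluster_test,
)
from .io import write_matrix, write_sidecar
from .prediction import (
    assemble_features, nested_cv_predict, permutation_significance,
)
from .richclub import (
    normalized_rich_club, sfc_class_engagement, stratify_gradient_by_class,
)
from .sfc import activation_windows, group_guided_sfc, level_sfc_features, sfc_profile, steps_to_reach

logger = logging.getLogger("connhier")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All pipeline tunables; serialized verbatim into output provenance."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    density: float = 0.10
    alpha: float = 0.5
    n_components: int = 10
    max_steps: int = 200
    theta: float = 1.0
    n_null: int = 1000
    n_perm_cluster: int = 10_000
    n_perm_prediction: int = 1000
    prediction_reps: int = 100
    prediction_perm_reps: int = 10
    use_gsr: bool = False
    use_timeseries: bool = False
    covariates: tuple[str, ...] = ("age", "site")
    richclub_mode: str = "weighted"
    run_prediction: bool = True
    run_cluster_test: bool = True
    run_permutation_significance: bool = False
    out_dir: str | None = None
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write(df: pd.DataFrame, out: Path | None, name: str) -> None:
    if out is not None:
        df.to_csv(out / name, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Run all enabled stages on a freshly simulated cohort.

    Returns a dict of in-memory results keyed by stage; if
    ``config.out_dir`` is set, each stage also writes its tables there.
    """
    t0 = time.time()
    out = Path(config.out_dir) if config.out_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": config}

    def tick(stage: str) -> None:
        logger.info("%-12s done at %6.1f s", stage, time.time() - t0)

    # --- simulate -----------------------------------------------------------
    space, manifest, connectomes, series = make_cohort(
        config.cohort, with_timeseries=config.use_timeseries or config.use_gsr
    )
    if config.use_gsr or config.use_timeseries:
        # exercise the Pearson path: correlation connectomes from sampled series
        new = []
        for ts in series:
            if config.use_gsr:
                ts = regress_global_signal(ts)
            new.append(correlation_connectome(ts))
        connectomes = new
    results.update(space=space, manifest=manifest, connectomes=connectomes)
    if out is not None:
        space.to_frame().to_csv(out / "nodes.tsv", sep="\t", index=False)
        manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
        write_sidecar(out / "run", {
            "config": dataclasses.asdict(config), "config_hash": config.config_hash(),
        })
    tick("simulate")

    # --- gradients ----------------------------------------------------------
    lv4 = space.level_indices(4)
    lv1 = space.level_indices(1)
    grads, template = cohort_gradients(
        connectomes, density=config.density, n_components=config.n_components,
        alpha=config.alpha, transmodal_nodes=lv4, unimodal_nodes=lv1,
    )
    g1 = np.stack([g.gradient(1) for g in grads])  # subjects x nodes
    results.update(gradients=grads, template=template, gradient1=g1)
    if out is not None:
        write_matrix(out / "gradient1.tsv", g1.T, list(space.node_ids))
    tick("gradients")

    # --- SFC ----------------------------------------------------------------
    groups = manifest["group"].to_numpy()
    pooled = group_average(connectomes)
    sparse_pooled = threshold_rows(pooled, config.density)
    seeds = space.all_seed_indices
    group_profile = sfc_profile(sparse_pooled, seeds, config.max_steps)
    ctrl_avg = group_average([c for c, g in zip(connectomes, groups) if g == "control"])
    ctrl_profile = sfc_profile(threshold_rows(ctrl_avg, config.density), seeds, config.max_steps)
    windows = activation_windows(ctrl_profile, space.hierarchy_level, config.theta)
    profiles, str_rows, level_maps = [], [], []
    for sid, c in zip(manifest["subject_id"], connectomes):
        p = sfc_profile(threshold_rows(c, config.density), seeds, config.max_steps)
        gp = group_guided_sfc(group_profile, p)
        profiles.append(gp)
        s2r = steps_to_reach(gp, space.hierarchy_level, config.theta)
        for lev, val in s2r.steps.items():
            str_rows.append({"subject_id": sid, "level": lev, "steps": val,
                             "censored": s2r.censored[lev]})
        level_maps.append(level_sfc_features(gp, windows))
    steps_df = pd.DataFrame(str_rows)
    results.update(sfc_profiles=profiles, steps_to_reach=steps_df,
                   sfc_windows=windows, sfc_level_maps=np.stack(level_maps))
    _write(steps_df, out, "steps_to_reach.tsv")
    tick("sfc")

    # --- rich club ----------------------------------------------------------
    rc = normalized_rich_club(
        sparse_pooled, n_null=config.n_null, seed=config.seed,
        mode=config.richclub_mode,
    )
    strat = stratify_gradient_by_class(g1, rc.node_class, groups)
    engagement = sfc_class_engagement(group_profile, rc.node_class, config.theta)
    results.update(richclub=rc, gradient_by_class=strat, class_engagement=engagement)
    if out is not None:
        rc.to_frame().to_csv(out / "richclub_curve.tsv", sep="\t", index=False)
        _write(strat, out, "gradient_by_class.tsv")
        _write(engagement, out, "class_engagement.tsv")
    tick("richclub")

    # --- group statistics on gradient 1 ------------------------------------
    design, names = build_design(manifest, covariates=config.covariates)
    nodestats = fit_node_models(g1, design, design_names=names)
    adjacency = knn_adjacency(space.coordinates, k=6)
    clusters = None
    if config.run_cluster_test:
        clusters = permutation_cluster_test(
            g1, manifest, adjacency, covariates=config.covariates,
            cdt=0.01, n_perm=config.n_perm_cluster, seed=config.seed,
        )
        nodestats.clusters = clusters
    commz = community_zscores(g1, space.community, groups)
    results.update(node_stats=nodestats, community_z=commz)
    if out is not None:
        nodestats.to_frame(list(space.node_ids)).to_csv(
            out / "node_stats.tsv", sep="\t", index=False)
        _write(commz, out, "community_z.tsv")
        if clusters is not None:
            clusters.drop(columns=["nodes"]).to_csv(
                out / "clusters.tsv", sep="\t", index=False)
    tick("stats")

    # --- connectivity distance ----------------------------------------------
    dmat = distance_matrix(space)
    ndm = mean_connectivity_distance(sparse_pooled, dmat)
    r_dist, p_dist = correlate_tmap_distance(nodestats.t, ndm)
    traj = np.stack([
        sfc_distance_trajectory(p, ndm, config.theta) for p in profiles
    ])
    traj_stats = sfc_distance_group_contrast(traj, groups)
    results.update(node_distance=ndm, tmap_distance_r=r_dist,
                   tmap_distance_p=p_dist, distance_trajectories=traj,
                   distance_trajectory_stats=traj_stats)
    _write(traj_stats, out, "distance_trajectory_stats.tsv")
    tick("distance")

    # --- prediction ---------------------------------------------------------
    if config.run_prediction:
        feats = assemble_features(
            g1, results["sfc_level_maps"], list(space.node_ids),
            manifest["subject_id"].tolist(),
            provenance={"density": config.density, "windows": {k: list(v) for k, v in windows.items()}},
        )
        Z, _ = build_design(manifest, covariates=config.covariates)
        Z = np.delete(Z, 1, axis=1)  # covariates only, no group column
        scores = manifest["score_total"].to_numpy(float)
        pred = nested_cv_predict(
            feats, scores, n_reps=config.prediction_reps, seed=config.seed,
            covariate_design=Z,
        )
        if config.run_permutation_significance:
            permutation_significance(
                feats, scores, pred, n_perm=config.n_perm_prediction,
                reps_per_perm=config.prediction_perm_reps, seed=config.seed,
                covariate_design=Z,
            )
        results["prediction"] = pred
        if out is not None:
            (out / "prediction.json").write_text(json.dumps({
                "median_r": pred.median_r, "median_mae": pred.median_mae,
                "permutation_p": pred.permutation_p, "scheme": pred.scheme,
                "provenance": pred.provenance,
            }, indent=2, default=str))
        tick("prediction")

    return results
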