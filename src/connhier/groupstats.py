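"""Node-level group inference.

Per-node ordinary least squares with age/site (and optional motion, sex,
whole-brain-connectivity) covariates, Benjamini-Hochberg FDR, a
maximum-cluster-size permutation test (covariates residualized out before
permuting group labels), community-level z-score summaries against the
control distribution, and Cohen's d effect sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform, pdist
from statsmodels.stats.multitest import multipletests

__all__ = [
    "build_design",
    "knn_adjacency",
    "NodeStatsResult",
    "fit_node_models",
    "fdr_correct",
    "cohens_d",
    "permutation_cluster_test",
    "community_zscores",
]


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Pooled-SD standardized mean difference (x minus y)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    sp = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2))
    return float((x.mean() - y.mean()) / sp) if sp > 0 else np.nan


def build_design(
    cohort: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "site"),
    group_col: str = "group",
    case_label: str = "case",
) -> tuple[np.ndarray, list[str]]:
    """Design matrix: intercept, binary group indicator, then covariates.

    ``site`` and ``sex`` expand to dummy indicators (first level reference);
    numeric covariates enter as-is. Raises on rank deficiency, naming the
    collinear columns.
    """
    n = len(cohort)
    cols = [np.ones(n), (cohort[group_col] == case_label).to_numpy(float)]
    names = ["intercept", "group"]
    for cov in covariates:
        vals = cohort[cov]
        if vals.dtype == object or str(vals.dtype) == "category" or cov in ("site", "sex"):
            levels = sorted(pd.unique(vals))
            for lev in levels[1:]:
                cols.append((vals == lev).to_numpy(float))
                names.append(f"{cov}[{lev}]")
        else:
            cols.append(vals.to_numpy(float))
            names.append(cov)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        r = 0
        for j in range(X.shape[1]):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                bad.append(names[j])
            r = rj
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    return X, names


def knn_adjacency(coordinates: np.ndarray, k: int = 6) -> np.ndarray:
    """Symmetric k-nearest-neighbor node adjacency on spatial coordinates."""
    D = squareform(pdist(np.asarray(coordinates, float)))
    np.fill_diagonal(D, np.inf)
    n = D.shape[0]
    A = np.zeros((n, n), dtype=bool)
    nn = np.argsort(D, axis=1)[:, :k]
    rows = np.repeat(np.arange(n), k)
    A[rows, nn.ravel()] = True
    return (A | A.T).astype(float)


@dataclass
class NodeStatsResult:
    """Per-node group-contrast statistics and (optionally) clusters."""

    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    significant: np.ndarray
    d: np.ndarray
    df_resid: int
    design_names: list[str] = field(default_factory=list)
    clusters: pd.DataFrame | None = None

    def to_frame(self, node_ids: list[str] | None = None) -> pd.DataFrame:
        n = len(self.t)
        return pd.DataFrame(
            {
                "node_id": node_ids or [f"n{i:04d}" for i in range(n)],
                "t": self.t,
                "p": self.p,
                "q": self.q,
                "significant": self.significant,
                "d": self.d,
            }
        )


def fit_node_models(
    values: np.ndarray,
    design: np.ndarray,
    design_names: list[str] | None = None,
    group_col_index: int = 1,
    q: float = 0.05,
) -> NodeStatsResult:
    """Per-node OLS of ``values`` (subjects x nodes) on a shared design.

    t is the group coefficient over its standard error; Cohen's d divides the
    covariate-adjusted group difference by the residual SD (reducing to the
    classical pooled d when the design is intercept + group only, up to the
    df convention of the residual variance).
    """
    Y = np.asarray(values, float)
    X = np.asarray(design, float)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError("need more subjects than design columns + 1")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank deficient")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(XtX_inv[group_col_index, group_col_index] * sigma2)
    zero_var = sigma2 <= np.finfo(float).eps * np.maximum((Y**2).mean(axis=0), 1e-30)
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} node(s) with zero residual variance",
                      RuntimeWarning)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(zero_var, np.nan, beta[group_col_index] / se)
        d = np.where(zero_var, np.nan, beta[group_col_index] / np.sqrt(sigma2))
    p = 2 * stats.t.sf(np.abs(t), dof)
    qvals, mask = fdr_correct(p, q=q)
    return NodeStatsResult(
        t=t, p=p, q=qvals, significant=mask, d=d, df_resid=dof,
        design_names=design_names or [],
    )


def fdr_correct(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up; NaN p-values are excluded and stay NaN."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        raise ValueError("no p-values to correct")
    ok = np.isfinite(p)
    qvals = np.full_like(p, np.nan)
    mask = np.zeros_like(p, dtype=bool)
    if ok.any():
        rej, qv = multipletests(p[ok], alpha=q, method="fdr_bh")[:2]
        qvals[ok] = qv
        mask[ok] = rej
    return qvals, mask


def _group_t(Y: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Vectorized two-sample t over nodes for binary label vector g."""
    n1 = g.sum()
    n0 = len(g) - n1
    m1 = (g @ Y) / n1
    m0 = ((1 - g) @ Y) / n0
    ss1 = (g @ Y**2) - n1 * m1**2
    ss0 = ((1 - g) @ Y**2) - n0 * m0**2
    s2 = (ss1 + ss0) / (n1 + n0 - 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (m1 - m0) / np.sqrt(s2 * (1 / n1 + 1 / n0))


def _cluster_sizes(mask: np.ndarray, adjacency: csr_matrix) -> tuple[np.ndarray, np.ndarray]:
    """Connected-component sizes among supra-threshold nodes."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return np.array([], dtype=int), np.full(mask.size, -1)
    sub = adjacency[np.ix_(idx, idx)]
    ncomp, labels = connected_components(csr_matrix(sub), directed=False)
    sizes = np.bincount(labels)
    full = np.full(mask.size, -1)
    full[idx] = labels
    return sizes, full


def permutation_cluster_test(
    values: np.ndarray,
    cohort: pd.DataFrame,
    adjacency: np.ndarray,
    covariates: tuple[str, ...] = ("age", "site"),
    cdt: float = 0.01,
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Max-cluster-size permutation test of the group contrast.

    Covariates are regressed out of every node first (full-sample
    residualization); group labels are then permuted and the two-sample t
    recomputed per node. Clusters are connected components of nodes with
    p < ``cdt``; each observed cluster's p-value is
    ``(1 + #{null max size >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    g = (cohort["group"] == "case").to_numpy(float)
    if g.sum() < 2 or (len(g) - g.sum()) < 2:
        raise ValueError("need at least 2 subjects per group")
    Y = np.asarray(values, float)
    if covariates:
        Xc, _ = build_design(cohort, covariates=covariates)
        Xc = np.delete(Xc, 1, axis=1)  # drop the group column: nuisance only
        beta, *_ = np.linalg.lstsq(Xc, Y, rcond=None)
        Y = Y - Xc @ beta
    dof = len(g) - 2
    t_crit = stats.t.isf(cdt / 2, dof)
    t_obs = _group_t(Y, g)
    obs_sizes, labels = _cluster_sizes(np.abs(t_obs) >= t_crit, csr_matrix(adjacency))
    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm)
    adj = csr_matrix(adjacency)
    for i in range(n_perm):
        gp = rng.permutation(g)
        tp = _group_t(Y, gp)
        sizes, _ = _cluster_sizes(np.abs(tp) >= t_crit, adj)
        null_max[i] = sizes.max() if sizes.size else 0
    rows = []
    for cid, size in enumerate(obs_sizes):
        pval = (1 + np.sum(null_max >= size)) / (1 + n_perm)
        rows.append({
            "cluster_id": cid,
            "size": int(size),
            "p": float(pval),
            "nodes": np.flatnonzero(labels == cid).tolist(),
        })
    out = pd.DataFrame(rows, columns=["cluster_id", "size", "p", "nodes"])
    out.attrs["null_max_sizes"] = null_max
    out.attrs["t_observed"] = t_obs
    return out


def community_zscores(
    values: np.ndarray,
    communities: np.ndarray,
    groups: np.ndarray,
    reference_group: str = "control",
    q: float = 0.05,
) -> pd.DataFrame:
    """Community-mean values z-scored against the reference-group distribution.

    Per community: each subject's community-mean value; case values z-scored
    by the reference group's mean/SD; two-sample t-test per community with
    BH-FDR across communities.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    ref = groups == reference_group
    if not ref.any():
        raise ValueError(f"reference group '{reference_group}' is empty")
    other = ~ref
    communities = np.asarray(communities)
    rows = []
    for com in sorted(set(int(c) for c in communities)):
        idx = np.flatnonzero(communities == com)
        if idx.size == 0:
            raise ValueError(f"community {com} absent from metadata")
        sub_means = values[:, idx].mean(axis=1)
        mu, sd = sub_means[ref].mean(), sub_means[ref].std(ddof=1)
        z = (sub_means[other].mean() - mu) / sd if sd > 0 else np.nan
        t, p = stats.ttest_ind(sub_means[other], sub_means[ref])
        rows.append({"community": com, "mean_case": sub_means[other].mean(),
                     "mean_ref": mu, "z": float(z), "t": float(t), "p": float(p)})
    df = pd.DataFrame(rows)
    qv, mask = fdr_correct(df["p"].to_numpy(), q=q)
    df["q"] = qv
    df["significant"] = mask
    return df
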