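"""Rich-club topology and its intersection with gradients and SFC.

The rich-club coefficient phi(k) measures how densely nodes of degree > k
connect among themselves. The binary variant is the subgraph edge density
``2 E_{>k} / (N_{>k} (N_{>k} - 1))``; the weighted variant divides the
subgraph's total weight by the sum of the E_{>k} strongest weights anywhere
in the network. Raw curves are normalized against degree-preserving rewired
null networks (double-edge swaps carrying weights with edges); k' is the
degree maximizing the normalized curve, rich-club nodes have degree >= k',
and the remaining nodes split into feeders (>= 10% of their edges incident
to rich nodes) and local nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import SparseConnectome
from .sfc import SFCProfile
from .groupstats import fdr_correct, cohens_d

try:  # optional JIT for the swap loop; pure-python fallback below
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None

__all__ = [
    "RichClubResult",
    "rich_club_curve",
    "rewire_preserving_degrees",
    "normalized_rich_club",
    "classify_nodes",
    "stratify_gradient_by_class",
    "sfc_class_engagement",
]


@dataclass
class RichClubResult:
    """phi(k), its rewired-null normalization, k', and the node taxonomy."""

    k: np.ndarray
    phi: np.ndarray  # NaN where undefined (fewer than 2 nodes above k)
    phi_norm: np.ndarray
    k_prime: int
    node_class: np.ndarray  # "rich" | "feeder" | "local"
    n_null: int
    null_seed: int
    mode: str = "weighted"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k, "phi": self.phi, "phi_norm": self.phi_norm})


def _graph_arrays(s: SparseConnectome | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(binary adjacency, symmetric weights) from a thresholded connectome."""
    if isinstance(s, SparseConnectome):
        W = s.symmetrized_weights()
    else:
        W = np.asarray(s, dtype=float)
        if np.any(W < 0):
            raise ValueError("negative weights not allowed in rich-club analysis")
        W = np.maximum(W, W.T)
    np.fill_diagonal(W, 0.0)
    A = (W > 0).astype(float)
    return A, W


def rich_club_curve(
    s: SparseConnectome | np.ndarray, mode: str = "weighted"
) -> tuple[np.ndarray, np.ndarray]:
    """phi(k) for k = 1 .. max degree; NaN where the >k subgraph is degenerate.

    Implemented by sorting nodes by descending degree: the subgraph above any
    threshold is a prefix of that order, so one O(n^2) cumulative pass yields
    the whole curve.
    """
    if mode not in ("binary", "weighted"):
        raise ValueError("mode must be 'binary' or 'weighted'")
    A, W = _graph_arrays(s)
    deg = A.sum(axis=1).astype(int)
    kmax = int(deg.max()) if deg.size else 0
    ks = np.arange(1, kmax + 1)
    order = np.argsort(-deg, kind="stable")
    deg_sorted = deg[order]
    # cumulative edge count / weight among the first m nodes of the order
    M = A[np.ix_(order, order)]
    Wo = W[np.ix_(order, order)]
    n = len(deg)
    cum_edges = np.zeros(n + 1)
    cum_w = np.zeros(n + 1)
    for m in range(1, n + 1):
        cum_edges[m] = cum_edges[m - 1] + M[m - 1, :m - 1].sum()
        cum_w[m] = cum_w[m - 1] + Wo[m - 1, :m - 1].sum()
    all_w_sorted = np.sort(W[np.triu_indices(n, 1)])[::-1]
    cum_top_w = np.concatenate([[0.0], np.cumsum(all_w_sorted)])
    phi = np.full(kmax, np.nan)
    for i, k in enumerate(ks):
        m = int(np.searchsorted(-deg_sorted, -k))  # nodes with degree > k
        if m < 2:
            continue
        E = cum_edges[m]
        if mode == "binary":
            phi[i] = 2.0 * E / (m * (m - 1))
        else:
            denom = cum_top_w[int(E)]
            phi[i] = cum_w[m] / denom if denom > 0 else np.nan
    return ks, phi


def _swap_loop_py(edges, adj, e1s, e2s, flips, target):
    """Sequential double-edge swaps on a boolean adjacency; edges keep their
    row identity (and hence their weight). Returns the number of swaps."""
    swaps = 0
    for t in range(len(e1s)):
        if swaps >= target:
            break
        e1, e2 = e1s[t], e2s[t]
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flips[t]:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = adj[b, a] = False
        adj[c, d] = adj[d, c] = False
        adj[a, d] = adj[d, a] = True
        adj[c, b] = adj[b, c] = True
        edges[e1, 0], edges[e1, 1] = a, d
        edges[e2, 0], edges[e2, 1] = c, b
        swaps += 1
    return swaps


if _njit is not None:
    _swap_loop_jit = _njit(cache=True)(_swap_loop_py)


def rewire_preserving_degrees(
    s: SparseConnectome | np.ndarray, n_swaps_per_edge: int = 10, seed: int = 0
) -> np.ndarray:
    """Degree-preserving randomization by double-edge swaps, weights carried.

    Swap (a,b),(c,d) -> (a,d),(c,b) when neither new edge exists and no
    self-loop arises; each edge keeps its weight through the swap. Returns
    the rewired symmetric weight matrix.
    """
    A, W = _graph_arrays(s)
    n = W.shape[0]
    iu, ju = np.where(np.triu(W, 1) > 0)
    weights = W[iu, ju].copy()
    edges = np.column_stack([iu, ju]).astype(np.int64)
    m = len(edges)
    if m < 2:
        raise ValueError("graph needs at least 2 edges to rewire")
    target = n_swaps_per_edge * m
    max_attempts = 20 * target
    rng = np.random.default_rng(seed)
    # pre-drawn random streams keep the two backends bit-identical
    e1s = rng.integers(0, m, max_attempts)
    e2s = rng.integers(0, m, max_attempts)
    flips = rng.random(max_attempts) < 0.5
    adj = A.astype(np.bool_)
    if _njit is not None:
        swaps = _swap_loop_jit(edges, adj, e1s, e2s, flips, target)
    else:
        swaps = _swap_loop_py(edges, adj, e1s, e2s, flips, target)
    if swaps == 0:
        warnings.warn("no swappable edge pairs found; null equals the original graph",
                      RuntimeWarning)
    out = np.zeros_like(W)
    out[edges[:, 0], edges[:, 1]] = weights
    out[edges[:, 1], edges[:, 0]] = weights
    return out


def normalized_rich_club(
    s: SparseConnectome | np.ndarray,
    n_null: int = 1000,
    seed: int = 0,
    mode: str = "weighted",
    n_swaps_per_edge: int = 10,
) -> RichClubResult:
    """phi(k) normalized by the mean over rewired nulls; k' = argmax phi_norm.

    Node classes are derived from k' via :func:`classify_nodes`.
    Deterministic given ``seed``.
    """
    ks, phi = rich_club_curve(s, mode=mode)
    null_phis = np.full((n_null, len(ks)), np.nan)
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(n_null)
    for i in range(n_null):
        Wn = rewire_preserving_degrees(s, n_swaps_per_edge=n_swaps_per_edge, seed=child[i])
        _, phin = rich_club_curve(Wn, mode=mode)
        null_phis[i, : len(phin)] = phin
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        null_mean = np.nanmean(null_phis, axis=0)
    phi_norm = np.where(null_mean > 0, phi / null_mean, np.nan)
    defined = np.flatnonzero(np.isfinite(phi_norm))
    if defined.size == 0:
        raise ValueError("phi_norm undefined at every degree level")
    k_prime = int(ks[defined[np.argmax(phi_norm[defined])]])
    node_class = classify_nodes(s, k_prime)
    return RichClubResult(
        k=ks, phi=phi, phi_norm=phi_norm, k_prime=k_prime,
        node_class=node_class, n_null=n_null, null_seed=int(seed), mode=mode,
    )


def classify_nodes(
    s: SparseConnectome | np.ndarray, k_prime: int, feeder_fraction: float = 0.10
) -> np.ndarray:
    """rich (degree >= k'), feeder (>= 10% of edges to rich nodes), local."""
    A, _ = _graph_arrays(s)
    deg = A.sum(axis=1)
    rich = deg >= k_prime
    if not rich.any():
        warnings.warn(f"no rich nodes at k' = {k_prime}; all non-rich set to local",
                      RuntimeWarning)
    to_rich = A[:, rich].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(deg > 0, to_rich / deg, 0.0)
    out = np.where(rich, "rich", np.where(frac >= feeder_fraction, "feeder", "local"))
    return out.astype(object)


def stratify_gradient_by_class(
    gradient1: np.ndarray,
    node_class: np.ndarray,
    groups: np.ndarray,
    q: float = 0.05,
) -> pd.DataFrame:
    """Group comparison of mean principal-gradient score within each node class.

    ``gradient1`` is subjects x nodes (aligned gradient-1 scores), ``groups``
    a per-subject label array with values "case"/"control". Two-sample
    t-tests per class, BH-FDR across the classes, Cohen's d; positive t means
    case > control.
    """
    gradient1 = np.asarray(gradient1, dtype=float)
    groups = np.asarray(groups)
    case = gradient1[groups == "case"]
    ctrl = gradient1[groups == "control"]
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError("need at least 2 subjects per group")
    rows = []
    for cls in ("rich", "feeder", "local"):
        idx = np.flatnonzero(node_class == cls)
        if idx.size == 0:
            warnings.warn(f"empty node class {cls}; skipped", RuntimeWarning)
            continue
        x = case[:, idx].mean(axis=1)
        y = ctrl[:, idx].mean(axis=1)
        t, p = stats.ttest_ind(x, y)
        rows.append({"node_class": cls, "n_nodes": idx.size, "t": float(t),
                     "p": float(p), "d": cohens_d(x, y)})
    df = pd.DataFrame(rows)
    qvals, mask = fdr_correct(df["p"].to_numpy(), q=q)
    df["q"] = qvals
    df["significant"] = mask
    return df


def sfc_class_engagement(
    p: SFCProfile, node_class: np.ndarray, theta: float = 1.0
) -> pd.DataFrame:
    """Per-step fraction of active (z >= theta) nodes in each class plus the
    rich-vs-local active-fraction ratio (NaN when no local node is active)."""
    if not np.isfinite(theta):
        raise ValueError("theta must be finite")
    node_class = np.asarray(node_class)
    active = np.nan_to_num(p.zmaps, nan=-np.inf) >= theta
    rows = []
    for l in range(1, p.max_steps + 1):
        row = {"step": l}
        for cls in ("rich", "feeder", "local"):
            idx = np.flatnonzero(node_class == cls)
            row[f"{cls}_frac"] = float(active[idx, l - 1].mean()) if idx.size else np.nan
        lf = row["local_frac"]
        row["rich_local_ratio"] = (
            row["rich_frac"] / lf if np.isfinite(lf) and lf > 0 else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)
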