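"""Functional connectome construction and transformation.

The pipeline's central object is the :class:`Connectome`: a symmetric
node-by-node matrix of Fisher-z transformed Pearson correlations between
regional rs-fMRI time series. Downstream stages consume row-thresholded
(:class:`SparseConnectome`) and cosine-affinity (:class:`AffinityMatrix`)
derivatives of it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TimeSeries",
    "Connectome",
    "SparseConnectome",
    "AffinityMatrix",
    "correlation_connectome",
    "regress_global_signal",
    "threshold_rows",
    "cosine_affinity",
    "group_average",
    "mean_connectivity",
]

#: Pearson r of +/-1 is clipped to +/-(1 - FISHER_CLIP) before atanh.
FISHER_CLIP = 1e-7

_SYMMETRY_TOL = 1e-10


def _as_node_ids(node_ids: Sequence[str] | None, n: int) -> list[str]:
    if node_ids is None:
        return [f"n{i:04d}" for i in range(n)]
    ids = [str(x) for x in node_ids]
    if len(ids) != n:
        raise ValueError(f"expected {n} node ids, got {len(ids)}")
    if len(set(ids)) != n:
        raise ValueError("node ids must be unique")
    return ids


@dataclass
class TimeSeries:
    """Node x timepoint real matrix of regional BOLD signals."""

    values: np.ndarray
    node_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D node x time matrix")
        if self.values.shape[1] < 2:
            raise ValueError("time series needs at least 2 timepoints")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")
        self.node_ids = _as_node_ids(self.node_ids or None, self.values.shape[0])

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def constant_rows(self) -> np.ndarray:
        """Indices of nodes whose series has zero variance."""
        return np.flatnonzero(self.values.std(axis=1) == 0)


@dataclass
class Connectome:
    """Symmetric node x node weight matrix in Fisher-z units; zero diagonal."""

    weights: np.ndarray
    node_ids: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("connectome weights must be square")
        if not np.all(np.isfinite(w)):
            raise ValueError("connectome weights contain non-finite values")
        if np.max(np.abs(w - w.T)) > _SYMMETRY_TOL:
            raise ValueError("connectome weights are not symmetric")
        w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0.0)
        self.weights = w
        self.node_ids = _as_node_ids(self.node_ids or None, w.shape[0])

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class SparseConnectome:
    """Row-thresholded connectome (possibly asymmetric) plus retained density."""

    weights: np.ndarray
    density: float
    node_ids: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.node_ids = _as_node_ids(self.node_ids or None, self.weights.shape[0])

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def binarized(self) -> np.ndarray:
        """Symmetric 0/1 adjacency: union of positive retained entries."""
        pos = self.weights > 0
        return (pos | pos.T).astype(float)

    def symmetrized_weights(self) -> np.ndarray:
        """Symmetric weighted adjacency: elementwise max of the row-thresholded
        matrix and its transpose (union symmetrization, weights kept)."""
        w = np.where(self.weights > 0, self.weights, 0.0)
        return np.maximum(w, w.T)


@dataclass
class AffinityMatrix:
    """Symmetric cosine-similarity matrix in [0, 1] with unit diagonal."""

    values: np.ndarray
    node_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.max(np.abs(v - v.T)) > 1e-8:
            raise ValueError("affinity matrix must be symmetric")
        self.values = 0.5 * (v + v.T)
        self.node_ids = _as_node_ids(self.node_ids or None, v.shape[0])

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def correlation_connectome(ts: TimeSeries) -> Connectome:
    """Fisher-z Pearson correlation connectome from regional time series.

    r = +/-1 (within numerical tolerance) is clipped to +/-(1 - 1e-7) so the
    z-transform stays finite.
    """
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints for a correlation connectome")
    const = ts.constant_rows()
    if const.size:
        names = ", ".join(ts.node_ids[i] for i in const[:5])
        raise ValueError(f"constant time series at node(s): {names}")
    r = np.corrcoef(ts.values)
    np.clip(r, -1.0 + FISHER_CLIP, 1.0 - FISHER_CLIP, out=r)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = 0.5 * (z + z.T)
    return Connectome(z, list(ts.node_ids), provenance={"transform": "fisher-z"})


def regress_global_signal(ts: TimeSeries) -> TimeSeries:
    """Global signal regression: residualize every node's series against the
    across-node mean series (with intercept)."""
    if ts.n_nodes < 2:
        raise ValueError("global signal regression needs at least 2 nodes")
    g = ts.values.mean(axis=0)
    if g.std() == 0:
        raise ValueError("global signal is constant; cannot regress")
    X = np.column_stack([np.ones_like(g), g])
    beta, *_ = np.linalg.lstsq(X, ts.values.T, rcond=None)
    resid = ts.values.T - X @ beta
    return TimeSeries(resid.T, list(ts.node_ids))


def threshold_rows(c: Connectome, density: float) -> SparseConnectome:
    """Keep the top ``ceil(density * (n - 1))`` off-diagonal weights per row.

    Values are retained unmodified (no renormalization). Ties at the cut are
    broken toward lower node indices so exactly k entries survive per row.
    """
    if not 0 < density <= 1:
        raise ValueError(f"density must be in (0, 1], got {density}")
    w = c.weights
    n = w.shape[0]
    k = math.ceil(density * (n - 1))
    out = np.zeros_like(w)
    masked = w.copy()
    np.fill_diagonal(masked, -np.inf)
    # stable sort descending => among ties, lower indices picked first
    order = np.argsort(-masked, axis=1, kind="stable")
    rows = np.repeat(np.arange(n), k)
    cols = order[:, :k].ravel()
    out[rows, cols] = w[rows, cols]
    return SparseConnectome(
        out, density, list(c.node_ids), provenance={"density": density, "k_per_row": k}
    )


def cosine_affinity(s: SparseConnectome) -> AffinityMatrix:
    """Cosine similarity between thresholded connectivity profiles.

    Negative similarities are clipped to 0 and the diagonal set to exactly 1,
    yielding a valid affinity for diffusion embedding.
    """
    w = s.weights
    norms = np.linalg.norm(w, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        names = ", ".join(s.node_ids[i] for i in zero[:5])
        raise ValueError(f"all-zero connectivity profile at node(s): {names}")
    a = (w @ w.T) / np.outer(norms, norms)
    np.clip(a, 0.0, 1.0, out=a)
    np.fill_diagonal(a, 1.0)
    return AffinityMatrix(0.5 * (a + a.T), list(s.node_ids))


def group_average(cs: Sequence[Connectome]) -> Connectome:
    """Entrywise mean connectome across subjects (identical node sets)."""
    cs = list(cs)
    if not cs:
        raise ValueError("no connectomes to average")
    ids = cs[0].node_ids
    for c in cs[1:]:
        if c.node_ids != ids:
            raise ValueError("connectomes have mismatched node ids")
    mean = np.mean([c.weights for c in cs], axis=0)
    return Connectome(mean, list(ids), provenance={"n_subjects": len(cs)})


def mean_connectivity(c: Connectome) -> float:
    """Mean off-diagonal weight; optional whole-brain-connectivity covariate."""
    n = c.n_nodes
    return float((c.weights.sum() - np.trace(c.weights)) / (n * (n - 1)))
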