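"""Connectivity-distance profiling.

Each node's *connectivity distance* is the mean spatial length of its
suprathreshold functional connections: binarize the thresholded connectome,
multiply by the pairwise distance matrix, and divide row sums by degree.
The node map relates group-difference t-maps to long- vs short-range
connectivity and tracks the spatial reach of SFC propagation across steps.
Distances are Euclidean from node coordinates by default; an externally
computed (e.g. geodesic) matrix can be supplied instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .connectome import SparseConnectome
from .cohort import NodeSpace
from .sfc import SFCProfile
from .groupstats import fdr_correct

__all__ = [
    "DistanceMatrix",
    "distance_matrix",
    "mean_connectivity_distance",
    "correlate_tmap_distance",
    "sfc_distance_trajectory",
    "sfc_distance_group_contrast",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative node x node distances, zero diagonal."""

    values: np.ndarray
    source: str = "euclidean_from_coordinates"
    node_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if np.max(np.abs(v - v.T)) > 1e-8 or np.any(v < 0):
            raise ValueError("distance matrix must be symmetric and non-negative")
        np.fill_diagonal(v, 0.0)
        self.values = v
        if not self.node_ids:
            self.node_ids = [f"n{i:04d}" for i in range(v.shape[0])]


def distance_matrix(space: NodeSpace) -> DistanceMatrix:
    """Pairwise Euclidean distances between node coordinates."""
    if space.coordinates is None:
        raise ValueError("node space has no coordinates")
    d = squareform(pdist(space.coordinates))
    return DistanceMatrix(d, source="euclidean_from_coordinates",
                          node_ids=list(space.node_ids))


def mean_connectivity_distance(s: SparseConnectome, d: DistanceMatrix) -> np.ndarray:
    """Per-node mean distance of suprathreshold connections.

    Binarized union-symmetrized positive connections; NaN (with a warning)
    for degree-zero nodes.
    """
    if s.n_nodes != d.values.shape[0]:
        raise ValueError("connectome and distance matrix differ in size")
    B = s.binarized()
    deg = B.sum(axis=1)
    zero = deg == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} node(s) with degree 0; distance undefined",
                      RuntimeWarning)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (B * d.values).sum(axis=1) / deg
    out[zero] = np.nan
    return out


def correlate_tmap_distance(tmap: np.ndarray, ndm: np.ndarray) -> tuple[float, float]:
    """Pearson correlation between a group-difference t-map and the node
    connectivity-distance map; positive r means longer-range nodes show
    larger (case > control) t values."""
    t = np.asarray(tmap, float)
    nd = np.asarray(ndm, float)
    ok = np.isfinite(t) & np.isfinite(nd)
    if ok.sum() < 3:
        raise ValueError("need at least 3 nodes with defined values")
    if t[ok].std() == 0 or nd[ok].std() == 0:
        raise ValueError("zero variance in t-map or distance map")
    r, p = stats.pearsonr(t[ok], nd[ok])
    return float(r), float(p)


def sfc_distance_trajectory(
    p: SFCProfile, ndm: np.ndarray, theta: float = 1.0, weighted: bool = False
) -> np.ndarray:
    """Mean connectivity distance of active (z >= theta) nodes per SFC step.

    ``weighted=True`` weights active nodes by their z value (shifted to be
    non-negative); default is the unweighted mean. NaN where no node active.
    """
    nd = np.asarray(ndm, float)
    out = np.full(p.max_steps, np.nan)
    z = np.nan_to_num(p.zmaps, nan=-np.inf)
    for l in range(p.max_steps):
        act = z[:, l] >= theta
        act &= np.isfinite(nd)
        if not act.any():
            continue
        if weighted:
            w = z[act, l] - theta + 1e-9
            out[l] = float(np.average(nd[act], weights=w))
        else:
            out[l] = float(nd[act].mean())
    return out


def sfc_distance_group_contrast(
    trajectories: np.ndarray, groups: np.ndarray, q: float = 0.05
) -> pd.DataFrame:
    """Two-sample t-test per step of subjects' SFC distance trajectories
    (case minus control), BH-FDR across steps."""
    T = np.asarray(trajectories, float)
    groups = np.asarray(groups)
    case, ctrl = T[groups == "case"], T[groups == "control"]
    rows = []
    for l in range(T.shape[1]):
        x, y = case[:, l], ctrl[:, l]
        x, y = x[np.isfinite(x)], y[np.isfinite(y)]
        if len(x) < 2 or len(y) < 2:
            rows.append({"step": l + 1, "t": np.nan, "p": np.nan,
                         "mean_case": np.nan, "mean_control": np.nan})
            continue
        t, p = stats.ttest_ind(x, y)
        rows.append({"step": l + 1, "t": float(t), "p": float(p),
                     "mean_case": x.mean(), "mean_control": y.mean()})
    df = pd.DataFrame(rows)
    qv, mask = fdr_correct(df["p"].to_numpy(), q=q)
    df["q"] = qv
    df["significant"] = mask
    return df
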