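"""Stepwise functional connectivity (SFC).

The SFC degree of node *i* at step *l* counts all walks of exact length *l*
from a seed set to *i* on the binarized, union-symmetrized thresholded
connectome — the power iteration ``v_l = A^l e_seeds``. Counts grow
exponentially with *l*, so each step's map is standardized across nodes
(z units); the iteration rescales ``v_l`` by a positive constant per step to
avoid overflow, which provably leaves z-maps unchanged. Individual maps can
be guided by a group-level profile (per-step elementwise product on a
min-max rescaled positive scale, then re-standardized), and per-level
steps-to-reach statistics summarize how many steps the propagation needs to
engage each tier of the cortical hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .connectome import SparseConnectome

__all__ = [
    "SFCProfile",
    "StepsToReach",
    "sfc_profile",
    "group_guided_sfc",
    "steps_to_reach",
    "activation_windows",
    "level_sfc_features",
]


@dataclass
class SFCProfile:
    """Node x step matrix of standardized SFC degree.

    ``zmaps[:, l-1]`` is the z-scored walk-count map at step ``l``; steps with
    zero across-node variance are stored as NaN columns and flagged.
    """

    zmaps: np.ndarray
    seed_set: np.ndarray
    raw_scale_log: np.ndarray  # per-step log of the positive rescaling applied
    node_ids: list[str] = field(default_factory=list)
    guided_by: str | None = None
    degenerate_steps: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        if not self.node_ids:
            self.node_ids = [f"n{i:04d}" for i in range(self.zmaps.shape[0])]

    @property
    def n_nodes(self) -> int:
        return self.zmaps.shape[0]

    @property
    def max_steps(self) -> int:
        return self.zmaps.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"step{l:03d}": self.zmaps[:, l - 1] for l in range(1, self.max_steps + 1)}
        return pd.DataFrame({"node_id": self.node_ids, **cols})


@dataclass
class StepsToReach:
    """Mean activation step per hierarchy level, censored at the profile length."""

    steps: dict[int, float]
    censored: dict[int, bool]
    theta: float
    max_steps: int


def _standardize(v: np.ndarray) -> tuple[np.ndarray, bool]:
    sd = v.std()
    if sd == 0 or not np.isfinite(sd):
        return np.full_like(v, np.nan), True
    return (v - v.mean()) / sd, False


def sfc_profile(
    s: SparseConnectome, seeds: np.ndarray | Sequence[int], max_steps: int = 200
) -> SFCProfile:
    """Walk-count SFC profile from a seed set.

    Uses the binarized union-symmetrized adjacency of the thresholded
    connectome. Raw counts are renormalized to unit maximum after each step
    (logged in ``raw_scale_log``) so the iteration never overflows.
    """
    seeds = np.asarray(seeds, dtype=int)
    if seeds.size == 0:
        raise ValueError("seed set is empty")
    A = s.binarized()
    n = A.shape[0]
    v = np.zeros(n)
    v[seeds] = 1.0
    zmaps = np.empty((n, max_steps))
    log_scales = np.empty(max_steps)
    degenerate = []
    log_acc = 0.0
    for l in range(1, max_steps + 1):
        v = A @ v
        m = v.max()
        if m <= 0:
            # seeds isolated: all-zero counts from here on
            zmaps[:, l - 1 :] = np.nan
            log_scales[l - 1 :] = log_acc
            degenerate.extend(range(l, max_steps + 1))
            break
        v = v / m
        log_acc += np.log(m)
        log_scales[l - 1] = log_acc
        z, flat = _standardize(v)
        zmaps[:, l - 1] = z
        if flat:
            degenerate.append(l)
    return SFCProfile(
        zmaps=zmaps,
        seed_set=seeds,
        raw_scale_log=log_scales,
        node_ids=list(s.node_ids),
        degenerate_steps=np.array(sorted(set(degenerate)), dtype=int),
    )


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = np.nanmin(v), np.nanmax(v)
    if hi == lo:
        return np.ones_like(v)
    return (v - lo) / (hi - lo)


def group_guided_sfc(group: SFCProfile, subject: SFCProfile) -> SFCProfile:
    """Two-step group-guided individual SFC.

    At each step both maps are min-max rescaled to [0, 1], multiplied
    elementwise, and the product re-standardized to z units. A constant group
    map therefore leaves the subject's z-map unchanged.
    """
    if group.node_ids != subject.node_ids:
        raise ValueError("group and subject profiles have mismatched nodes")
    if group.max_steps != subject.max_steps:
        raise ValueError("group and subject profiles have mismatched step counts")
    if not np.array_equal(np.sort(group.seed_set), np.sort(subject.seed_set)):
        raise ValueError("group and subject profiles have mismatched seed sets")
    L = subject.max_steps
    zmaps = np.empty_like(subject.zmaps)
    degenerate = []
    for l in range(1, L + 1):
        g, u = group.zmaps[:, l - 1], subject.zmaps[:, l - 1]
        if np.any(np.isnan(g)) or np.any(np.isnan(u)):
            zmaps[:, l - 1] = np.nan
            degenerate.append(l)
            continue
        prod = _minmax(g) * _minmax(u)
        z, flat = _standardize(prod)
        zmaps[:, l - 1] = z
        if flat:
            degenerate.append(l)
    return SFCProfile(
        zmaps=zmaps,
        seed_set=subject.seed_set.copy(),
        raw_scale_log=subject.raw_scale_log.copy(),
        node_ids=list(subject.node_ids),
        guided_by="group",
        degenerate_steps=np.array(sorted(set(degenerate)), dtype=int),
    )


def steps_to_reach(
    p: SFCProfile,
    levels: np.ndarray,
    theta: float = 1.0,
    require_levels: Sequence[int] | None = None,
) -> StepsToReach:
    """Mean number of steps until each hierarchy level's nodes first exceed
    ``theta`` z units; nodes never reaching are censored at the profile length.

    ``require_levels`` declares the expected level labels; a declared level
    with no nodes raises.
    """
    if not np.isfinite(theta):
        raise ValueError("theta must be finite")
    levels = np.asarray(levels)
    if require_levels is not None:
        for lev in require_levels:
            if not np.any(levels == lev):
                raise ValueError(f"hierarchy level {lev} has no nodes")
    L = p.max_steps
    above = np.nan_to_num(p.zmaps, nan=-np.inf) >= theta
    first = np.where(above.any(axis=1), above.argmax(axis=1) + 1, L)
    out_steps: dict[int, float] = {}
    out_cens: dict[int, bool] = {}
    for lev in sorted(set(int(x) for x in levels)):
        idx = np.flatnonzero(levels == lev)
        if idx.size == 0:
            raise ValueError(f"hierarchy level {lev} has no nodes")
        out_steps[lev] = float(first[idx].mean())
        out_cens[lev] = bool(np.all(~above[idx].any(axis=1)))
    return StepsToReach(steps=out_steps, censored=out_cens, theta=theta, max_steps=L)


def activation_windows(
    control_template: SFCProfile, levels: np.ndarray, theta: float = 1.0
) -> dict[int, tuple[int, int]]:
    """Per-level activation windows estimated from a control-group template.

    For each level the window is the contiguous step range, containing the
    step of maximal level-mean z, over which the level mean stays >= theta.
    If the level mean never crosses theta the window collapses to the argmax
    step alone.
    """
    levels = np.asarray(levels)
    windows: dict[int, tuple[int, int]] = {}
    for lev in sorted(set(int(x) for x in levels)):
        idx = np.flatnonzero(levels == lev)
        mean_z = np.nanmean(control_template.zmaps[idx], axis=0)
        peak = int(np.nanargmax(mean_z))
        above = mean_z >= theta
        if not above[peak]:
            windows[lev] = (peak + 1, peak + 1)
            continue
        lo = peak
        while lo > 0 and above[lo - 1]:
            lo -= 1
        hi = peak
        while hi < mean_z.size - 1 and above[hi + 1]:
            hi += 1
        windows[lev] = (lo + 1, hi + 1)
    return windows


def level_sfc_features(
    p: SFCProfile, windows: Mapping[int, tuple[int, int]]
) -> np.ndarray:
    """Average each subject's z-maps over per-level activation windows.

    Returns a node x level matrix (columns ordered by level label): the four
    SFC feature maps of the severity-prediction stage.
    """
    cols = []
    for lev in sorted(windows):
        lo, hi = windows[lev]
        if not (1 <= lo <= hi <= p.max_steps):
            raise ValueError(f"window {windows[lev]} for level {lev} outside [1, {p.max_steps}]")
        cols.append(np.nanmean(p.zmaps[:, lo - 1 : hi], axis=1))
    return np.column_stack(cols)
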