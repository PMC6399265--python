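"""Synthetic multi-site cohorts with a planted cortical hierarchy.

The generator emulates, at parcel scale, the structure the analysis pipeline
is designed to detect: seven functional communities mapped onto four
hierarchy levels (1 sensory/somatomotor, 2 attention/salience,
3 frontoparietal, 4 DMN/limbic), a smooth unimodal-to-transmodal hierarchy
score per node, distance-dependent connectivity, and two planted case-group
effects — hierarchy *compression* (gamma < 1 pulls hierarchy scores toward
the middle, flattening the gradient) and *long-range attenuation* (rho
down-weights connections beyond a distance cutoff). Site scale/offset,
age, sex and motion confounds, and symptom scores linearly coupled to the
planted effects complete the cohort.

Every subject's data derive from a random stream keyed by
``(master_seed, site, group, index-within-cell)``, so adding subjects never
perturbs existing ones.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .connectome import Connectome, TimeSeries

__all__ = [
    "NodeSpace",
    "SubjectSpec",
    "CohortConfig",
    "make_node_space",
    "make_subject_connectome",
    "make_timeseries",
    "make_symptom_scores",
    "make_cohort",
    "DEFAULT_COMMUNITY_SIZES",
    "COMMUNITY_LEVEL",
]

# Yeo-style 7-community taxonomy -> Mesulam hierarchy level.
# DMN is deliberately the largest community (as in real parcellations), so
# that transmodal cortex hosts the network's most broadly connected nodes.
COMMUNITY_NAMES = {
    1: "visual",
    2: "somatomotor",
    3: "dorsal_attention",
    4: "salience",
    5: "limbic",
    6: "frontoparietal",
    7: "default",
}
COMMUNITY_LEVEL = {1: 1, 2: 1, 3: 2, 4: 2, 5: 4, 6: 3, 7: 4}

#: Per-community node fractions for the default 200-node space.
DEFAULT_COMMUNITY_FRACTIONS = {1: 0.15, 2: 0.15, 3: 0.125, 4: 0.125, 5: 0.10, 6: 0.15, 7: 0.20}
DEFAULT_COMMUNITY_SIZES = {c: int(round(f * 200)) for c, f in DEFAULT_COMMUNITY_FRACTIONS.items()}

# Community hierarchy-score centers: ordered by level and spread so that,
# with the default within-community jitter, adjacent communities overlap and
# the unimodal-to-transmodal axis is continuous rather than 4 discrete steps
# (as in real cortex, where the principal gradient is smooth).
_COMMUNITY_H_CENTER = {1: 0.05, 2: 0.17, 3: 0.32, 4: 0.47, 5: 0.76, 6: 0.62, 7: 0.90}


@dataclass
class NodeSpace:
    """Node-level ground truth: hierarchy score, community, level, coordinates."""

    n_nodes: int
    hierarchy_score: np.ndarray  # in [0, 1]; 0 unimodal, 1 transmodal
    community: np.ndarray  # labels 1..7
    hierarchy_level: np.ndarray  # labels 1..4
    coordinates: np.ndarray  # (n, 3), arbitrary length units
    seed_nodes: dict[str, np.ndarray]  # "V1"/"A1"/"S1" -> node indices
    node_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.node_ids:
            self.node_ids = [f"n{i:04d}" for i in range(self.n_nodes)]
        h = self.hierarchy_score
        if h.min() < 0 or h.max() > 1:
            raise ValueError("hierarchy_score must lie in [0, 1]")
        lv = {int(c): int(l) for c, l in zip(self.community, self.hierarchy_level)}
        for c, l in zip(self.community, self.hierarchy_level):
            if lv[int(c)] != int(l):
                raise ValueError("each community must map to exactly one hierarchy level")
        sets = [set(v.tolist()) for v in self.seed_nodes.values()]
        if any(not s for s in sets):
            raise ValueError("seed subsets must be non-empty")
        if len(set().union(*sets)) != sum(len(s) for s in sets):
            raise ValueError("seed subsets must be disjoint")

    @property
    def all_seed_indices(self) -> np.ndarray:
        return np.sort(np.concatenate([v for v in self.seed_nodes.values()]))

    def level_indices(self, level: int) -> np.ndarray:
        return np.flatnonzero(self.hierarchy_level == level)

    def to_frame(self) -> pd.DataFrame:
        seed_label = np.array([""] * self.n_nodes, dtype=object)
        for name, idx in self.seed_nodes.items():
            seed_label[idx] = name
        return pd.DataFrame(
            {
                "node_id": self.node_ids,
                "community": self.community,
                "hierarchy_level": self.hierarchy_level,
                "hierarchy_score": self.hierarchy_score,
                "x": self.coordinates[:, 0],
                "y": self.coordinates[:, 1],
                "z": self.coordinates[:, 2],
                "seed_label": seed_label,
            }
        )


@dataclass
class SubjectSpec:
    """One subject's demographics, confounds and planted effect sizes."""

    subject_id: str
    group: str  # "control" | "case"
    site: str
    age: float
    sex: str
    motion: float  # mean framewise displacement surrogate, mm
    gamma: float = 1.0  # gradient compression (<1 = compressed)
    rho: float = 0.0  # long-range attenuation fraction

    def __post_init__(self) -> None:
        if self.group not in ("control", "case"):
            raise ValueError(f"group must be control|case, got {self.group}")
        if self.motion < 0:
            raise ValueError("motion must be >= 0")
        if not 0 < self.gamma <= 1.5:
            raise ValueError("gamma must be in (0, 1.5]")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")


@dataclass
class CohortConfig:
    """Generative parameters of a two-group multi-site cohort.

    Defaults define the package's reference study conditions: 2 sites,
    case-group compression gamma = 0.7 and long-range attenuation rho = 0.3,
    subject-level weight noise, and mild site/motion confounds.
    """

    n_per_group_per_site: int = 25
    sites: tuple[str, ...] = ("siteA", "siteB")
    noise_sd: float = 0.06
    tau_h: float = 0.30  # hierarchy decay length of exp(-|dh|/tau_h)
    beta_c: float = 0.10  # within-community weight bonus (secondary to hierarchy)
    hub_strength: float = 1.2  # network-wide transmodal hub term amplitude
    d0: float = 35.0  # long-range cutoff, same units as coordinates
    gamma_control: float = 1.0
    gamma_case: float = 0.7
    rho_control: float = 0.0
    rho_case: float = 0.3
    effect_sd: float = 0.10  # between-subject severity heterogeneity of gamma/rho
    site_scale_sd: float = 0.02
    site_offset_sd: float = 0.02
    motion_coef: float = 0.15  # additive noise SD per mm of motion
    symptom_coefs: tuple[float, ...] = (20.0, 15.0)  # on (1-gamma, rho)
    symptom_intercept: float = 4.0
    symptom_noise_sd: float = 2.2
    symptom_r2_target: float | None = 0.5  # overrides symptom_noise_sd if set
    timepoints: int | None = None
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group_per_site < 1:
            raise ValueError("n_per_group_per_site must be >= 1")
        for name in ("noise_sd", "effect_sd", "site_scale_sd", "site_offset_sd",
                     "motion_coef", "symptom_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def make_node_space(
    n_nodes: int = 200,
    community_sizes: dict[int, int] | None = None,
    seed: int = 0,
    cluster_sd: float = 4.0,
    cluster_dispersion: float = 3.0,
    h_jitter_sd: float = 0.08,
) -> NodeSpace:
    """Lay out ``n_nodes`` parcels in 7 spatially clustered communities.

    Hierarchy scores are smooth around community centers ordered by level;
    community centroids are placed along a spatial axis proportional to their
    hierarchy center, so Euclidean distance correlates positively with
    hierarchy separation (a stand-in for cortical geodesic distance).
    """
    if n_nodes < 20:
        raise ValueError("need at least 20 nodes")
    if community_sizes is None:
        sizes = {c: int(round(f * n_nodes)) for c, f in DEFAULT_COMMUNITY_FRACTIONS.items()}
        sizes[7] += n_nodes - sum(sizes.values())  # absorb rounding in DMN
    else:
        sizes = dict(community_sizes)
    if sum(sizes.values()) != n_nodes or any(v < 1 for v in sizes.values()):
        raise ValueError(
            f"community sizes {sizes} inconsistent with n_nodes={n_nodes}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    community = np.concatenate([np.full(sizes[c], c) for c in sorted(sizes)])
    level = np.array([COMMUNITY_LEVEL[c] for c in community])

    h = np.empty(n_nodes)
    coords = np.empty((n_nodes, 3))
    start = 0
    for c in sorted(sizes):
        m = sizes[c]
        center_h = _COMMUNITY_H_CENTER[c]
        h[start:start + m] = np.clip(
            center_h + rng.normal(0, h_jitter_sd, m), 0.0, 1.0
        )
        # community centroid: concave placement along x (sensory communities
        # mutually distant, transmodal ones packed — mimicking dispersed
        # primary cortices vs a spatially coherent apex), mild y/z spread to
        # avoid perfect collinearity
        centroid = np.array(
            [140.0 * np.sqrt(center_h), 12.0 * np.cos(2.4 * c), 6.0 * np.sin(1.7 * c)]
        )
        # sensory clusters are spatially dispersed (primary cortices span
        # distant sheets), the transmodal apex is compact
        sd_c = cluster_sd * (1.0 + cluster_dispersion * (1.0 - center_h))
        coords[start:start + m] = centroid + rng.normal(0, sd_c, (m, 3))
        start += m

    # level ordering of community means holds by construction: center gaps
    # between levels are >= 0.2, far beyond the default jitter sd
    seed_nodes = {}
    vis = np.flatnonzero(community == 1)
    smo = np.flatnonzero(community == 2)
    n_seed = max(1, min(3, len(vis), len(smo) // 2))
    seed_nodes["V1"] = vis[:n_seed]
    # A1 and S1 both sit in sensory/somatomotor cortex: disjoint picks
    seed_nodes["A1"] = smo[:n_seed]
    seed_nodes["S1"] = smo[n_seed:2 * n_seed]
    return NodeSpace(
        n_nodes=n_nodes,
        hierarchy_score=h,
        community=community,
        hierarchy_level=level,
        coordinates=coords,
        seed_nodes=seed_nodes,
    )


def _site_effects(site: str, sites: Sequence[str], config: CohortConfig) -> tuple[float, float]:
    """Deterministic per-site global scale and additive offset."""
    sites = list(sites)
    # unknown sites (user-supplied cohorts) get a stable name-derived stream
    idx = sites.index(site) if site in sites else (
        int.from_bytes(site.encode(), "little") % 1_000_003
    )
    rng = np.random.default_rng(np.random.SeedSequence([config.master_seed, 10_000 + idx]))
    scale = 1.0 + rng.normal(0, config.site_scale_sd)
    offset = rng.normal(0, config.site_offset_sd)
    return scale, offset


def make_subject_connectome(
    space: NodeSpace,
    spec: SubjectSpec,
    config: CohortConfig,
    seed: int = 0,
) -> Connectome:
    """Generate one subject's weight matrix from the planted model.

    The planted weight model is a local hierarchy kernel plus a community
    bonus plus a network-wide transmodal hub term::

        w_ij = exp(-|h'_i - h'_j| / tau_h) + beta_c * [c_i = c_j]
               + hub_strength * (h'_i**2 + h'_j**2) / 2 + noise

    with compressed hierarchy ``h' = 0.5 + gamma * (h - 0.5)``. The hub term
    lets apex (DMN) nodes enter even distant rows' strongest connections —
    the long-range rich-club connectivity of real transmodal cortex — and
    shrinks under compression, so cases lose hub reach. Pairs farther than
    ``d0`` are multiplied by ``(1 - rho)``; then site scale/offset and
    motion-proportional noise are applied, the matrix symmetrized and the
    diagonal zeroed.
    """
    rng = np.random.default_rng(seed)
    h = 0.5 + spec.gamma * (space.hierarchy_score - 0.5)
    dh = np.abs(h[:, None] - h[None, :])
    w = np.exp(-dh / config.tau_h)
    same_comm = space.community[:, None] == space.community[None, :]
    w = w + config.beta_c * same_comm
    h2 = h**2
    w = w + config.hub_strength * 0.5 * (h2[:, None] + h2[None, :])
    if config.noise_sd > 0:
        noise = rng.normal(0, config.noise_sd, w.shape)
        w = w + 0.5 * (noise + noise.T)
    dist = np.linalg.norm(space.coordinates[:, None, :] - space.coordinates[None, :, :], axis=-1)
    w = np.where(dist > config.d0, w * (1.0 - spec.rho), w)
    scale, offset = _site_effects(spec.site, config.sites, config)
    w = scale * w + offset
    if config.motion_coef > 0 and spec.motion > 0:
        mnoise = rng.normal(0, config.motion_coef * spec.motion, w.shape)
        w = w + 0.5 * (mnoise + mnoise.T)
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    return Connectome(
        w,
        list(space.node_ids),
        provenance={"subject_id": spec.subject_id, "gamma": spec.gamma, "rho": spec.rho,
                    "site": spec.site},
    )


def make_timeseries(
    connectome: Connectome, timepoints: int, seed: int = 0, min_eig: float = 1e-6
) -> TimeSeries:
    """Sample zero-mean multivariate-normal series whose correlation target is
    the (rescaled, PSD-repaired) connectome.

    The weight matrix is mapped to a correlation-like target by unit-diagonal
    rescaling; eigenvalues below ``min_eig`` are raised by diagonal loading
    and the matrix re-normalized to unit diagonal.
    """
    w = connectome.weights.copy()
    n = w.shape[0]
    scale = max(np.abs(w).max(), 1e-12)
    c = 0.9 * w / scale  # off-diagonal magnitudes < 1
    np.fill_diagonal(c, 1.0)
    evals = np.linalg.eigvalsh(c)
    lo = evals.min()
    if lo < min_eig:
        load = (min_eig - lo) + 1e-12
        c = c + load * np.eye(n)
        d = np.sqrt(np.diag(c))
        c = c / np.outer(d, d)
        if np.linalg.eigvalsh(c).min() <= 0:
            raise np.linalg.LinAlgError(
                "PSD repair failed: target too far from positive definite "
                f"(min eigenvalue {lo:.3g})"
            )
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(c + 1e-12 * np.eye(n))
    x = L @ rng.standard_normal((n, timepoints))
    return TimeSeries(x, list(connectome.node_ids))


def make_symptom_scores(
    cohort: pd.DataFrame,
    features: np.ndarray,
    config: CohortConfig,
    seed: int = 0,
    score_name: str = "score_total",
) -> pd.DataFrame:
    """Assign symptom scores to case subjects as a linear function of planted
    per-subject features plus Gaussian noise; controls stay missing.

    If ``config.symptom_r2_target`` is set, the noise SD is derived from the
    linear predictor's variance so the generating model's population R^2 hits
    the target; the achieved (sample) R^2 is recorded in the returned frame's
    ``attrs``.
    """
    feats = np.atleast_2d(np.asarray(features, dtype=float))
    if feats.shape[0] != len(cohort):
        raise ValueError("features must have one row per subject")
    coefs = np.asarray(config.symptom_coefs, dtype=float)
    if feats.shape[1] != coefs.size:
        raise ValueError(f"expected {coefs.size} features, got {feats.shape[1]}")
    case = (cohort["group"] == "case").to_numpy()
    fv = feats[case].std(axis=0)
    if np.any((fv == 0) & (coefs != 0)):
        raise ValueError("zero feature variance with nonzero symptom coefficient")
    lin = config.symptom_intercept + feats @ coefs
    if config.symptom_r2_target is not None:
        sig_sd = lin[case].std()
        r2 = config.symptom_r2_target
        noise_sd = sig_sd * np.sqrt((1 - r2) / r2) if sig_sd > 0 else config.symptom_noise_sd
    else:
        noise_sd = config.symptom_noise_sd
    rng = np.random.default_rng(seed)
    raw = lin + rng.normal(0, noise_sd, len(cohort))
    score = np.clip(np.round(raw), 0, None)
    out = cohort.copy()
    out[score_name] = np.where(case, score, np.nan)
    if case.sum() > 2 and np.var(raw[case]) > 0:
        achieved = 1.0 - np.var(raw[case] - lin[case]) / np.var(raw[case])
    else:
        achieved = np.nan
    out.attrs["symptom_provenance"] = {
        "coefs": coefs.tolist(),
        "intercept": config.symptom_intercept,
        "noise_sd": float(noise_sd),
        "achieved_r2": float(achieved),
        "seed": int(seed),
    }
    return out


def _subject_seed(
    master_seed: int, site_idx: int, group_idx: int, k: int
) -> np.random.SeedSequence:
    """Seed stream keyed by (site, group, within-cell index): enlarging the
    cohort never perturbs existing subjects' data."""
    return np.random.SeedSequence([master_seed, site_idx, group_idx, k])


def make_cohort(
    config: CohortConfig | None = None,
    space: NodeSpace | None = None,
    with_timeseries: bool = False,
) -> tuple[NodeSpace, pd.DataFrame, list[Connectome], list[TimeSeries] | None]:
    """Generate the full two-group multi-site cohort.

    Returns the node space, the subject manifest (with symptom scores for
    cases), per-subject connectomes, and optionally per-subject time series.
    Bit-reproducible for a fixed ``config.master_seed``.
    """
    config = config or CohortConfig()
    if space is None:
        space = make_node_space(seed=config.master_seed)
    rows, specs, subject_streams = [], [], []
    idx = 0
    for si, site in enumerate(config.sites):
        for gi, group in enumerate(("control", "case")):
            for k in range(config.n_per_group_per_site):
                streams = _subject_seed(config.master_seed, si, gi, k).spawn(3)
                subject_streams.append(streams)
                rng = np.random.default_rng(streams[0])
                gamma_mu = config.gamma_case if group == "case" else config.gamma_control
                rho_mu = config.rho_case if group == "case" else config.rho_control
                gamma = float(np.clip(rng.normal(gamma_mu, config.effect_sd), 0.05, 1.5))
                rho = float(np.clip(rng.normal(rho_mu, config.effect_sd), 0.0, 0.95))
                spec = SubjectSpec(
                    subject_id=f"sub-{idx:04d}",
                    group=group,
                    site=site,
                    age=float(np.clip(rng.normal(20.0, 7.0), 7.0, 55.0)),
                    sex="M" if rng.random() < 0.8 else "F",
                    motion=float(np.clip(rng.gamma(4.0, 0.025), 0.01, 0.3)),
                    gamma=gamma,
                    rho=rho,
                )
                specs.append(spec)
                rows.append({**asdict(spec)})
                idx += 1
    manifest = pd.DataFrame(rows)
    connectomes = []
    series = [] if with_timeseries else None
    for spec, streams in zip(specs, subject_streams):
        conn_seed, ts_seed = streams[1], streams[2]
        connectomes.append(make_subject_connectome(space, spec, config, seed=conn_seed))
        if with_timeseries:
            T = config.timepoints or (space.n_nodes + 50)
            series.append(make_timeseries(connectomes[-1], T, seed=ts_seed))
    planted = np.column_stack(
        [1.0 - manifest["gamma"].to_numpy(), manifest["rho"].to_numpy()]
    )
    case = (manifest["group"] == "case").to_numpy()
    score_cfg = config
    if np.any(planted[case].std(axis=0) == 0):
        # effect-free cohort: no planted severity signal exists; scores are
        # intercept + noise so downstream prediction sees pure null data
        score_cfg = dataclasses.replace(
            config, symptom_coefs=tuple(0.0 for _ in config.symptom_coefs),
            symptom_r2_target=None,
        )
    manifest = make_symptom_scores(
        manifest, planted, score_cfg,
        seed=np.random.SeedSequence([config.master_seed, 99_999]).generate_state(1)[0],
    )
    return space, manifest, connectomes, series
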