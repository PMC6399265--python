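"""Connectome gradients via diffusion map embedding.

The embedding builds the density-normalized diffusion operator from a cosine
affinity matrix: with degrees ``d_i = sum_j a_ij``, the anisotropic kernel is
``W'_ij = a_ij / (d_i d_j)^alpha`` (``alpha = 0.5`` by default, removing the
influence of sampling density), and ``P`` is the row-normalized Markov matrix
of ``W'``. Gradients are the non-trivial right eigenvectors of ``P``, ordered
by eigenvalue; at diffusion time ``t = 0`` columns are scaled by the
multiscale factor ``lambda / (1 - lambda)``, at ``t > 0`` by ``lambda**t``.
Individual embeddings are aligned to a group template by Procrustes rotation
(orthogonal transform, no scaling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import connected_components
from scipy.linalg import orthogonal_procrustes

from .connectome import AffinityMatrix, Connectome, group_average, threshold_rows, cosine_affinity

__all__ = [
    "GradientSet",
    "GradientTemplate",
    "diffusion_embedding",
    "variance_explained",
    "procrustes_align",
    "cohort_gradients",
]


@dataclass
class GradientSet:
    """Node x component embedding scores plus the spectrum that produced them."""

    scores: np.ndarray
    eigenvalues: np.ndarray  # descending, non-trivial spectrum
    alpha: float
    diffusion_time: float
    node_ids: list[str] = field(default_factory=list)
    aligned_to: str | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.node_ids:
            self.node_ids = [f"n{i:04d}" for i in range(self.scores.shape[0])]
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("gradient scores must be finite")

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    @property
    def variance_explained(self) -> np.ndarray:
        return variance_explained(self.eigenvalues)

    def gradient(self, i: int = 1) -> np.ndarray:
        """1-based component accessor; ``gradient(1)`` is the principal gradient."""
        return self.scores[:, i - 1]


@dataclass
class GradientTemplate:
    """Group-level gradient component template."""

    scores: np.ndarray
    eigenvalues: np.ndarray
    node_ids: list[str]
    provenance: dict = field(default_factory=dict)


def diffusion_embedding(
    a: AffinityMatrix,
    n_components: int = 10,
    alpha: float = 0.5,
    diffusion_time: float = 0.0,
) -> GradientSet:
    """Diffusion map embedding of a symmetric affinity matrix.

    Solved through the symmetric conjugate of the Markov operator, so the
    spectrum is real and the trivial constant eigenvector (eigenvalue 1) can
    be identified and dropped exactly.
    """
    W = np.asarray(a.values, dtype=float)
    n = W.shape[0]
    if n_components > n - 1:
        raise ValueError("n_components must be <= n_nodes - 1")
    n_comp, labels = connected_components(W > 0, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels).tolist()
        raise ValueError(f"affinity graph is disconnected; component sizes {sizes}")

    d = W.sum(axis=1)
    if alpha > 0:
        W = W / np.outer(d**alpha, d**alpha)
    d2 = W.sum(axis=1)
    # symmetric conjugate M = D^-1/2 W' D^-1/2 shares eigenvalues with P
    inv_sqrt = 1.0 / np.sqrt(d2)
    M = W * np.outer(inv_sqrt, inv_sqrt)
    M = 0.5 * (M + M.T)
    evals, evecs = scipy.linalg.eigh(M)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # right eigenvectors of P: psi = D^-1/2 u, normalized against the trivial one
    psi = evecs * inv_sqrt[:, None]
    psi = psi / psi[:, [0]]  # trivial component becomes the constant 1 vector
    lam = evals[1 : n_components + 1]
    vecs = psi[:, 1 : n_components + 1]

    degenerate = bool(np.all(np.abs(lam) < 1e-10))
    if degenerate:
        warnings.warn("degenerate spectrum: all non-trivial eigenvalues ~ 0", RuntimeWarning)
        scale = np.zeros_like(lam)
    elif diffusion_time == 0:
        scale = lam / (1.0 - np.clip(lam, None, 1.0 - 1e-12))
    else:
        scale = np.sign(lam) * np.abs(lam) ** diffusion_time
    scores = vecs * scale[None, :]
    return GradientSet(
        scores=scores,
        eigenvalues=lam,
        alpha=alpha,
        diffusion_time=diffusion_time,
        node_ids=list(a.node_ids),
        degenerate=degenerate,
    )


def variance_explained(eigenvalues: np.ndarray) -> np.ndarray:
    """Fraction of (non-trivial) spectrum variance per component: lambda / sum."""
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size == 0 or np.all(lam == 0):
        raise ValueError("variance_explained needs a non-zero spectrum")
    if np.any(lam < -1e-12):
        raise ValueError("eigenvalues must be non-negative")
    lam = np.clip(lam, 0.0, None)
    return lam / lam.sum()


def procrustes_align(
    subject: GradientSet, template: GradientTemplate, n_align: int | None = None
) -> tuple[GradientSet, float]:
    """Orthogonal Procrustes alignment of a subject's components to a template.

    Columns are centered, a rotation/reflection (no scaling) minimizing the
    Frobenius distance is applied, and the disparity (residual squared
    Frobenius distance) returned alongside the aligned set.
    """
    if subject.node_ids != list(template.node_ids):
        raise ValueError("subject and template node sets differ")
    k = n_align or min(subject.n_components, template.scores.shape[1])
    if k > subject.n_components or k > template.scores.shape[1]:
        raise ValueError("n_align exceeds available components")
    mu = template.scores[:, :k].mean(axis=0)
    X = subject.scores[:, :k] - subject.scores[:, :k].mean(axis=0)
    Y = template.scores[:, :k] - mu
    R, _ = orthogonal_procrustes(X, Y)
    aligned = X @ R
    disparity = float(np.sum((aligned - Y) ** 2))
    aligned = aligned + mu  # back into template space
    out = GradientSet(
        scores=aligned,
        eigenvalues=subject.eigenvalues[:k],
        alpha=subject.alpha,
        diffusion_time=subject.diffusion_time,
        node_ids=list(subject.node_ids),
        aligned_to=template.provenance.get("template_id", "template"),
        degenerate=subject.degenerate,
    )
    return out, disparity


def _embed_connectome(
    c: Connectome, density: float, n_components: int, alpha: float, diffusion_time: float
) -> GradientSet:
    return diffusion_embedding(
        cosine_affinity(threshold_rows(c, density)),
        n_components=n_components,
        alpha=alpha,
        diffusion_time=diffusion_time,
    )


def cohort_gradients(
    connectomes: Sequence[Connectome],
    density: float = 0.10,
    n_components: int = 10,
    n_align: int | None = None,
    alpha: float = 0.5,
    diffusion_time: float = 0.0,
    transmodal_nodes: np.ndarray | None = None,
    unimodal_nodes: np.ndarray | None = None,
) -> tuple[list[GradientSet], GradientTemplate]:
    """Embed every subject and align to the pooled group-average template.

    The template's principal-gradient orientation is fixed so transmodal
    anchor nodes score above unimodal anchors (eigenvector sign is otherwise
    arbitrary); individual alignment then inherits the orientation.
    """
    if len(connectomes) < 2:
        raise ValueError("cohort_gradients needs at least 2 subjects")
    avg = group_average(connectomes)
    temp_set = _embed_connectome(avg, density, n_components, alpha, diffusion_time)
    scores = temp_set.scores.copy()
    if transmodal_nodes is not None and unimodal_nodes is not None:
        g1 = scores[:, 0]
        if g1[transmodal_nodes].mean() < g1[unimodal_nodes].mean():
            scores[:, 0] = -g1
    template = GradientTemplate(
        scores=scores,
        eigenvalues=temp_set.eigenvalues,
        node_ids=list(temp_set.node_ids),
        provenance={"template_id": "pooled-average", "density": density, "alpha": alpha},
    )
    aligned = []
    for c in connectomes:
        gs = _embed_connectome(c, density, n_components, alpha, diffusion_time)
        ags, _ = procrustes_align(gs, template, n_align)
        aligned.append(ags)
    return aligned, template
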