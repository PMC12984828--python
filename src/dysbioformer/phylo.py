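"""Phylogenetic kernel and spectral taxon features.

Evolutionary relatedness enters the model through the exponential distance
kernel K_ij = exp(-lambda * d_ij), with d_ij the patristic (branch-length)
distance between taxa i and j. A fixed, reproducible per-taxon feature
vector h_i is extracted spectrally: h = top-m eigenvectors of K scaled by
sqrt(eigenvalue) (negative eigenvalues clipped to zero), so that h h^T is
the best rank-m PSD approximation of the clipped kernel and inner products
between taxon features approximate their kernel similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import PhyloTree, ValidationError

log = logging.getLogger(__name__)

#: Kernel decay rate per branch-length unit.
DEFAULT_LAMBDA_K = 1.0


@dataclass
class PhyloModel:
    """Tree-derived taxon geometry: distances d, kernel K, spectral features h."""

    taxa: list[str]
    d: np.ndarray
    K: np.ndarray
    lambda_k: float
    h: np.ndarray | None = None  # (n_taxa, m)

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if self.d.shape != (n, n) or self.K.shape != (n, n):
            raise ValueError("d/K shape mismatch with taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance diagonal must be zero")
        if not np.allclose(self.K, self.K.T):
            raise ValueError("kernel must be symmetric")
        if not np.allclose(np.diag(self.K), 1.0):
            raise ValueError("kernel diagonal must be 1")
        if (self.K <= 0).any() or (self.K > 1 + 1e-12).any():
            raise ValueError("kernel entries must lie in (0, 1]")

    @property
    def m(self) -> int:
        return 0 if self.h is None else self.h.shape[1]


def phylo_kernel(tree: PhyloTree, taxa: list[str], lambda_k: float = DEFAULT_LAMBDA_K) -> PhyloModel:
    """Build the exponential patristic-distance kernel over ``taxa``."""
    if lambda_k < 0:
        raise ValueError("lambda_k must be >= 0")
    missing = set(taxa) - set(tree.leaf_labels)
    if missing:
        raise ValidationError(f"taxa missing from tree: {sorted(missing)[:5]}")
    order, d = tree.distance_matrix(list(taxa))
    K = np.exp(-lambda_k * d)
    np.fill_diagonal(K, 1.0)
    return PhyloModel(order, d, K, lambda_k)


def kernel_features(model: PhyloModel, m: int) -> PhyloModel:
    """Attach spectral features h (taxa x m) so that h h^T ~ K at rank m.

    Eigenvalues sorted descending, negatives clipped to 0 before scaling;
    each eigenvector's sign is fixed by making its largest-magnitude entry
    positive, so the features are deterministic.
    """
    n = len(model.taxa)
    if not 1 <= m <= n:
        raise ValueError(f"m must be in [1, {n}], got {m}")
    w, v = np.linalg.eigh(model.K)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    w = np.clip(w, 0.0, None)
    for j in range(v.shape[1]):
        k = np.argmax(np.abs(v[:, j]))
        if v[k, j] < 0:
            v[:, j] = -v[:, j]
    h = v[:, :m] * np.sqrt(w[:m])
    return PhyloModel(list(model.taxa), model.d, model.K, model.lambda_k, h)


def identity_fallback(taxa: list[str], m: int | None = None) -> PhyloModel:
    """No-tree fallback: K = identity-like, h = one-hot taxon identity.

    Used when no phylogeny is supplied; the model degrades to tree-agnostic
    tokens. Logged prominently because it removes the evolutionary prior.
    """
    n = len(taxa)
    log.warning("phylo: no tree supplied; using one-hot taxon features (K ~ identity)")
    eps = 1e-12  # keep entries in (0, 1] per the kernel contract
    K = np.full((n, n), eps)
    np.fill_diagonal(K, 1.0)
    d = -np.log(K)
    np.fill_diagonal(d, 0.0)
    h = np.eye(n) if m is None else np.eye(n)[:, :m]
    return PhyloModel(list(taxa), d, K, 1.0, h)


def mean_similarity(model: PhyloModel) -> np.ndarray:
    """Per-taxon mean off-diagonal kernel similarity K-bar."""
    n = len(model.taxa)
    if n == 1:
        log.warning("mean_similarity: single taxon; defining K-bar = 1")
        return np.ones(1)
    return (model.K.sum(axis=1) - np.diag(model.K)) / (n - 1)
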