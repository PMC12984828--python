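"""Per-sample multisets of compositionally weighted taxon tokens.

Each sample becomes an unordered collection of per-taxon feature vectors:
for every taxon present in the sample (raw count > 0), the raw token is

    e_i = concat(phylo_h_i, clr_i, w_i),   w_i = log(1 + x*_i * Kbar_i),

where phylo_h_i is the spectral phylogenetic feature vector, clr_i the
harmonized CLR abundance, x*_i the zero-replaced fraction and Kbar_i the
taxon's mean phylogenetic similarity. Tokens are standardized per feature
dimension with global moments fitted on training samples only, then
projected into the latent token space, z_i = w_i * (W_e e~_i + b_e); the
compositional weight both scales the projected token and survives as a
feature, so abundance information outlives standardization.

Token sets carry no order semantics: every downstream consumer must be
invariant to row permutation (enforced by the model's attention design and
tested end to end).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .compositional import CompositionMatrix
from .io_formats import CountTable
from .phylo import PhyloModel, mean_similarity

log = logging.getLogger(__name__)

_SIGMA_FLOOR = 1e-6
DEFAULT_TOKEN_DIM = 128


@dataclass
class TokenSet:
    """Padded batch of per-sample token multisets.

    ``features`` is (n_samples, max_tokens, feature_dim); ``mask`` is True
    exactly where a real token lives; ``taxon_idx`` maps tokens back to taxa
    (-1 on padding). ``phylo_dim`` is the width of the leading phylogenetic
    slice of the feature vector.
    """

    sample_ids: list[str]
    features: np.ndarray
    weights: np.ndarray
    mask: np.ndarray
    taxon_idx: np.ndarray
    phylo_dim: int
    normalized: bool = False

    def __post_init__(self) -> None:
        B, T, F = self.features.shape
        assert self.weights.shape == (B, T)
        assert self.mask.shape == (B, T)
        assert self.taxon_idx.shape == (B, T)
        assert (self.mask | (self.taxon_idx == -1)).all()

    @property
    def feature_dim(self) -> int:
        return self.features.shape[2]

    def subset(self, sample_ids: list[str]) -> "TokenSet":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return TokenSet(
            list(sample_ids),
            self.features[idx],
            self.weights[idx],
            self.mask[idx],
            self.taxon_idx[idx],
            self.phylo_dim,
            self.normalized,
        )

    def permuted(self, sample: int, rng: np.random.Generator) -> "TokenSet":
        """Return a copy with one sample's token rows randomly permuted."""
        perm = rng.permutation(self.features.shape[1])
        out = TokenSet(
            list(self.sample_ids),
            self.features.copy(),
            self.weights.copy(),
            self.mask.copy(),
            self.taxon_idx.copy(),
            self.phylo_dim,
            self.normalized,
        )
        out.features[sample] = out.features[sample][perm]
        out.weights[sample] = out.weights[sample][perm]
        out.mask[sample] = out.mask[sample][perm]
        out.taxon_idx[sample] = out.taxon_idx[sample][perm]
        return out


@dataclass
class TokenizerState:
    """Training-fitted feature moments plus the token projection.

    The projection (W_e, b_e) is seed-initialized here and trained jointly
    with the network; mu/sigma are frozen transform parameters.
    """

    mu: np.ndarray
    sigma: np.ndarray
    W_e: np.ndarray  # (feature_dim, token_dim)
    b_e: np.ndarray  # (token_dim,)
    fitted_on: list[str] = field(default_factory=list)

    @property
    def token_dim(self) -> int:
        return self.W_e.shape[1]


def compositional_weight(fraction, k_bar):
    """w_i = log(1 + x*_i * Kbar_i) — abundance magnitude weighted by the
    taxon's averaged phylogenetic similarity."""
    return np.log1p(np.asarray(fraction) * np.asarray(k_bar))


def raw_token_features(
    clr_col: np.ndarray,
    frac_col: np.ndarray,
    present: np.ndarray,
    phylo: PhyloModel,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample token features for the present taxa.

    Returns (features (n_present, m+2), weights (n_present,), taxon indices).
    Row order follows taxon order, but carries no semantics downstream.
    """
    if phylo.h is None:
        raise ValueError("phylo model has no features; run kernel_features first")
    idx = np.where(present)[0]
    k_bar = mean_similarity(phylo)
    w = compositional_weight(frac_col[idx], k_bar[idx])
    feats = np.concatenate(
        [phylo.h[idx], clr_col[idx, None], w[:, None]], axis=1
    )
    return feats, w, idx


def build_token_sets(
    clr: CompositionMatrix,
    frac: CompositionMatrix,
    counts: CountTable,
    phylo: PhyloModel,
    include_absent_taxa: bool = False,
) -> TokenSet:
    """Assemble the padded raw (un-normalized) token batch for all samples."""
    if clr.mode != "clr" or frac.mode != "fraction":
        raise ValueError("expected clr-mode and fraction-mode inputs")
    if list(clr.taxa) != list(phylo.taxa) or list(frac.taxa) != list(phylo.taxa):
        raise ValueError("taxa order mismatch between matrices and phylo model")
    B = len(clr.samples)
    per_sample = []
    for j in range(B):
        present = (
            np.ones(len(counts.taxa), dtype=bool)
            if include_absent_taxa
            else counts.counts[:, j] > 0
        )
        per_sample.append(
            raw_token_features(clr.values[:, j], frac.values[:, j], present, phylo)
        )
    T = max(f.shape[0] for f, _, _ in per_sample)
    F = per_sample[0][0].shape[1]
    features = np.zeros((B, T, F))
    weights = np.zeros((B, T))
    mask = np.zeros((B, T), dtype=bool)
    taxon_idx = np.full((B, T), -1, dtype=np.int64)
    for j, (f, w, idx) in enumerate(per_sample):
        n = f.shape[0]
        features[j, :n] = f
        weights[j, :n] = w
        mask[j, :n] = True
        taxon_idx[j, :n] = idx
    return TokenSet(list(clr.samples), features, weights, mask, taxon_idx, phylo.h.shape[1])


def fit_normalizer(
    tokens: TokenSet, token_dim: int = DEFAULT_TOKEN_DIM, seed: int = 42
) -> TokenizerState:
    """Fit per-dimension global moments over all real training tokens and
    seed-initialize the Xavier-uniform token projection."""
    real = tokens.features[tokens.mask]
    if real.shape[0] < 2:
        raise ValueError("need at least 2 training tokens to fit the normalizer")
    mu = real.mean(axis=0)
    sigma = real.std(axis=0)
    constant = sigma < _SIGMA_FLOOR
    if constant.any():
        log.warning("fit_normalizer: %d constant feature dim(s); sigma floored", int(constant.sum()))
    sigma = np.maximum(sigma, _SIGMA_FLOOR)
    F = tokens.feature_dim
    rng = np.random.default_rng(seed)
    limit = np.sqrt(6.0 / (F + token_dim))
    W_e = rng.uniform(-limit, limit, size=(F, token_dim))
    b_e = np.zeros(token_dim)
    return TokenizerState(mu, sigma, W_e, b_e, list(tokens.sample_ids))


def apply_normalizer(tokens: TokenSet, state: TokenizerState) -> TokenSet:
    """Standardize token features with frozen training moments."""
    feats = (tokens.features - state.mu) / state.sigma
    feats[~tokens.mask] = 0.0
    return TokenSet(
        list(tokens.sample_ids),
        feats,
        tokens.weights,
        tokens.mask,
        tokens.taxon_idx,
        tokens.phylo_dim,
        normalized=True,
    )


def project_tokens(
    norm_features: np.ndarray, weights: np.ndarray, state: TokenizerState
) -> np.ndarray:
    """z_i = w_i * (W_e e~_i + b_e) — the latent multiset tokens."""
    norm_features = np.asarray(norm_features, dtype=float)
    if norm_features.shape[-1] != state.W_e.shape[0]:
        raise ValueError(
            f"feature dim {norm_features.shape[-1]} does not match projection "
            f"input {state.W_e.shape[0]}"
        )
    z = norm_features @ state.W_e + state.b_e
    return np.asarray(weights)[..., None] * z
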