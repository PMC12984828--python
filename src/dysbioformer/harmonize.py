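"""Empirical-Bayes location-scale batch correction across studies.

Multi-study collections carry per-study (batch) shifts from differing
protocols and platforms. Correction standardizes each taxon within its
batch and re-expresses it on the pooled scale,

    x~_ij = ((x_ij - mu_hat_b) / sigma_hat_b) * sigma* + mu*,

where the per-batch moments are shrunk toward the pooled cross-batch
moments with strength lambda (lambda -> 0: plain location-scale
standardization; lambda -> inf: identity-like full shrinkage to the pool):

    mu_hat_b    = (n_b * mean_b + lambda * mu_pool) / (n_b + lambda)
    sigma_hat_b^2 = (var_b + lambda * var_pool) / (1 + lambda)

Disease labels never enter fitting (label-free harmonization), and the
fitted model records the samples it was estimated on so cross-validation
drivers can assert train/test disjointness.

``alignment_score`` is the moment-matching diagnostic: per batch, the summed
squared difference between batch-wise and pooled per-taxon (mean, SD) pairs;
zero iff the batch moments coincide with the pooled ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .compositional import CompositionMatrix
from .io_formats import SampleMetadata

log = logging.getLogger(__name__)

DEFAULT_LAMBDA = 0.01
_SD_FLOOR = 1e-6


@dataclass
class BatchModel:
    """Fitted per-(taxon, batch) moments plus global targets."""

    taxa: list[str]
    batches: list[str]
    mu_b: np.ndarray  # (n_taxa, n_batches) shrunken batch means
    sd_b: np.ndarray  # (n_taxa, n_batches) shrunken batch SDs (floored)
    mu_star: np.ndarray  # (n_taxa,) pooled means
    sd_star: np.ndarray  # (n_taxa,) pooled SDs
    lam: float
    fitted_on: list[str] = field(default_factory=list)
    identity_batches: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if (self.sd_b <= 0).any():
            raise ValueError("batch SDs must be > 0 (floored at 1e-6)")


def estimate_batch_params(
    X: CompositionMatrix, meta: SampleMetadata, lam: float = DEFAULT_LAMBDA
) -> BatchModel:
    """Fit shrunken per-batch moments on CLR values.

    Batches with fewer than 2 samples are excluded from fitting; correction
    falls back to identity for them (logged).
    """
    if X.mode != "clr":
        raise ValueError("estimate_batch_params expects clr-mode input")
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    sample_ids = list(X.samples)
    studies = meta.studies(sample_ids)
    batches = sorted(set(studies))
    V = X.values
    mu_pool = V.mean(axis=1)
    var_pool = V.var(axis=1)

    n_t = len(X.taxa)
    mu_b = np.tile(mu_pool[:, None], (1, len(batches)))
    sd_b = np.tile(np.sqrt(var_pool)[:, None], (1, len(batches)))
    identity_batches: set[str] = set()
    for b_idx, b in enumerate(batches):
        cols = np.where(studies == b)[0]
        if cols.size < 2:
            identity_batches.add(b)
            log.warning(
                "estimate_batch_params: batch %r has %d sample(s); "
                "excluded from fitting (identity correction)",
                b,
                cols.size,
            )
            continue
        raw_mu = V[:, cols].mean(axis=1)
        raw_var = V[:, cols].var(axis=1)
        n_b = cols.size
        mu_b[:, b_idx] = (n_b * raw_mu + lam * mu_pool) / (n_b + lam)
        var_shrunk = (raw_var + lam * var_pool) / (1.0 + lam)
        sd_b[:, b_idx] = np.sqrt(var_shrunk)
    sd_b = np.maximum(sd_b, _SD_FLOOR)
    sd_star = np.maximum(np.sqrt(var_pool), _SD_FLOOR)
    model = BatchModel(
        list(X.taxa), batches, mu_b, sd_b, mu_pool, sd_star, lam, list(sample_ids),
        identity_batches,
    )
    return model


def apply_batch_correction(
    X: CompositionMatrix,
    model: BatchModel,
    meta: SampleMetadata,
    unknown_batch: str = "error",
) -> CompositionMatrix:
    """Transform CLR values with frozen batch parameters.

    May be applied to held-out samples (transform-only contract). Batches
    unseen at fit time either raise (default) or pass through unchanged
    (``unknown_batch="identity"``) — the latter is what leave-study-out
    evaluation requires, since the held-out study's batch is never fitted.
    """
    if X.mode != "clr":
        raise ValueError("apply_batch_correction expects clr-mode input")
    if model.taxa != list(X.taxa):
        raise ValueError("taxa mismatch between model and input")
    if unknown_batch not in ("error", "identity"):
        raise ValueError("unknown_batch must be 'error' or 'identity'")
    studies = meta.studies(X.samples)
    out = X.values.copy()
    batch_index = {b: i for i, b in enumerate(model.batches)}
    for b in sorted(set(studies)):
        cols = np.where(studies == b)[0]
        if b not in batch_index or b in model.identity_batches:
            if b not in batch_index and unknown_batch == "error":
                raise ValueError(f"batch {b!r} was not fitted; no parameters to apply")
            continue  # identity
        i = batch_index[b]
        z = (X.values[:, cols] - model.mu_b[:, [i]]) / model.sd_b[:, [i]]
        out[:, cols] = z * model.sd_star[:, None] + model.mu_star[:, None]
    # the per-taxon affine map preserves within-batch sample ordering but
    # leaves column zero-sums only approximate; flagged via validate=False
    return CompositionMatrix(list(X.taxa), list(X.samples), out, "clr", validate=False)


def alignment_score(
    X: CompositionMatrix, meta: SampleMetadata
) -> tuple[dict[str, float], float]:
    """Moment-matching misalignment per batch (lower is better-aligned).

    score(b) = sum_i (mu_bi - mu_i)^2 + (sd_bi - sd_i)^2 over taxa i, with
    pooled moments as the reference. Returns (per-batch scores, total).
    """
    if X.mode != "clr":
        raise ValueError("alignment_score expects clr-mode input")
    studies = meta.studies(X.samples)
    mu_pool = X.values.mean(axis=1)
    sd_pool = X.values.std(axis=1)
    scores: dict[str, float] = {}
    for b in sorted(set(studies)):
        cols = np.where(studies == b)[0]
        mu_b = X.values[:, cols].mean(axis=1)
        sd_b = X.values[:, cols].std(axis=1)
        scores[b] = float(((mu_b - mu_pool) ** 2).sum() + ((sd_b - sd_pool) ** 2).sum())
    return scores, float(sum(scores.values()))
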