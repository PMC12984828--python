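"""Attention-derived taxonomic biomarker ranking.

Two attention signals are aggregated per taxon over a sample set:

* ``sab_score`` — incoming attention mass: for each sample, layer and head,
  the column sums of the row-softmax SAB weights (how much the rest of the
  community attends TO each token), averaged over real query rows, layers,
  heads, and the samples in which the taxon is present;
* ``pma_score`` — the mean seed-to-taxon softmax weight gamma over seeds,
  heads and samples (per sample and seed these sum to 1 over taxa:
  attention mass is conserved).

The combined score averages the min-max-scaled components (their raw scales
differ). Direction (enriched/depleted) is annotated from the case-control
CLR mean difference in the data — attention magnitudes carry no sign.
Cross-fold stability is the frequency with which a taxon enters the top-k
of each fold's ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compositional import CompositionMatrix
from .io_formats import SampleMetadata
from .set_model import AttentionTrace, DysbioNet
from .tokens import TokenSet


@dataclass
class AttributionReport:
    taxa: list[str]
    sab_score: np.ndarray
    pma_score: np.ndarray
    combined: np.ndarray
    rank: np.ndarray  # 1 = most important
    direction: list[str] = field(default_factory=list)  # enriched/depleted/na
    warning: str | None = None

    def top_k(self, k: int = 10) -> list[str]:
        order = np.argsort(self.rank)
        return [self.taxa[i] for i in order[:k]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon": self.taxa,
                "sab_score": self.sab_score,
                "pma_score": self.pma_score,
                "combined": self.combined,
                "rank": self.rank,
                "direction": self.direction or ["na"] * len(self.taxa),
            }
        ).sort_values("rank")


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi - lo < 1e-12:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def aggregate_trace(
    trace: AttentionTrace, n_taxa: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Accumulate per-taxon SAB incoming mass and PMA gamma over one batch.

    Returns (sab_sum, pma_sum, presence_count) arrays over the taxon axis.
    """
    sab_sum = np.zeros(n_taxa)
    pma_sum = np.zeros(n_taxa)
    present = np.zeros(n_taxa)
    B, T = trace.mask.shape
    for b in range(B):
        real = trace.mask[b]
        idx = trace.taxon_idx[b][real]
        n_real = int(real.sum())
        if n_real == 0:
            continue
        present[idx] += 1
        if trace.sab_alphas:
            # (layers, heads, T, T) -> incoming mass per key token, averaged
            # over real query rows, layers and heads
            per_token = np.zeros(n_real)
            for alpha in trace.sab_alphas:
                a = alpha[b][:, real][:, :, real]  # (heads, T_real_q, T_real_k)
                per_token += a.sum(axis=1).mean(axis=0) / n_real
            sab_sum[idx] += per_token / len(trace.sab_alphas)
        # gamma: (heads, S, T) -> mean over heads and seeds
        g = trace.pma_gamma[b][:, :, real]
        pma_sum[idx] += g.mean(axis=(0, 1))
    return sab_sum, pma_sum, present


def taxon_importance(
    net: DysbioNet,
    tokens: TokenSet,
    taxa: list[str],
    clr: CompositionMatrix | None = None,
    meta: SampleMetadata | None = None,
    trained: bool = True,
    batch_size: int = 64,
) -> AttributionReport:
    """Score every taxon by aggregated attention over ``tokens``.

    Taxa absent from a sample contribute no mass for it; scores average over
    the samples where the taxon is present. If ``clr`` and ``meta`` are
    given, enrichment direction is annotated from the case-control CLR mean
    difference.
    """
    n_taxa = len(taxa)
    sab_sum = np.zeros(n_taxa)
    pma_sum = np.zeros(n_taxa)
    present = np.zeros(n_taxa)
    ids = tokens.sample_ids
    for start in range(0, len(ids), batch_size):
        sub = tokens.subset(ids[start : start + batch_size])
        _, trace = net.forward(sub, trace=True)
        s, p, c = aggregate_trace(trace, n_taxa)
        sab_sum += s
        pma_sum += p
        present += c
    seen = present > 0
    sab = np.where(seen, sab_sum / np.maximum(present, 1), np.nan)
    pma = np.where(seen, pma_sum / np.maximum(present, 1), np.nan)
    combined = (_minmax(np.nan_to_num(sab)) + _minmax(np.nan_to_num(pma))) / 2.0
    # ranks: a permutation of 1..n_taxa, best combined score first
    order = np.argsort(-combined, kind="stable")
    rank = np.empty(n_taxa, dtype=int)
    rank[order] = np.arange(1, n_taxa + 1)

    direction: list[str] = []
    if clr is not None and meta is not None:
        labels = meta.labels(clr.samples)
        case = labels != "control"
        if case.any() and (~case).any():
            diff = clr.values[:, case].mean(axis=1) - clr.values[:, ~case].mean(axis=1)
            direction = ["enriched" if d > 0 else "depleted" for d in diff]
    warning = None
    if not trained:
        warning = "untrained model: attention scores are not meaningful"
        warnings.warn(warning, stacklevel=2)
    return AttributionReport(list(taxa), sab, pma, combined, rank, direction, warning)


@dataclass
class StabilityResult:
    taxa: list[str]
    frequency: np.ndarray  # fraction of folds with top-k membership
    mean_combined: np.ndarray
    order: np.ndarray  # taxa indices sorted by (frequency, mean combined)

    def ranked_taxa(self) -> list[str]:
        return [self.taxa[i] for i in self.order]


def stability_selection(reports: list[AttributionReport], k: int = 10) -> StabilityResult:
    """Rank taxa by how often they enter each fold's attribution top-k.

    Fold reports with differing taxa sets are aligned by union; absence
    counts as non-membership. Ties break by mean combined score.
    """
    if len(reports) < 2:
        raise ValueError("stability selection needs >= 2 fold reports")
    union: list[str] = []
    for r in reports:
        for t in r.taxa:
            if t not in union:
                union.append(t)
    idx = {t: i for i, t in enumerate(union)}
    member = np.zeros(len(union))
    combined = np.zeros(len(union))
    counted = np.zeros(len(union))
    for r in reports:
        top = set(r.top_k(k))
        for t, c in zip(r.taxa, r.combined):
            combined[idx[t]] += c
            counted[idx[t]] += 1
            if t in top:
                member[idx[t]] += 1
    frequency = member / len(reports)
    mean_combined = combined / np.maximum(counted, 1)
    order = np.lexsort((-mean_combined, -frequency))
    return StabilityResult(union, frequency, mean_combined, order)
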