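"""Compositional normalization: zero replacement, CSS scaling, CLR transform.

Microbial count vectors carry only relative information (constant-sum
constraint), so raw counts are first closed to strictly positive fractions
with a pseudo-count delta, x*_i = (x_i + delta) / sum_j (x_j + delta), and
then mapped to unconstrained Euclidean coordinates with the centered
log-ratio, CLR(x_i) = ln(x_i / g(x)) with g the per-sample geometric mean.
Cumulative-sum scaling (CSS) is available as an alternative library-size
normalization; the model pipeline consumes CLR geometry by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import CountTable

log = logging.getLogger(__name__)

#: Table-level default pseudo-count for zero replacement.
DEFAULT_DELTA = 1e-6


@dataclass
class CompositionMatrix:
    """Taxon-by-sample matrix of fractions, CSS-scaled counts, or CLR values."""

    taxa: list[str]
    samples: list[str]
    values: np.ndarray
    mode: str  # {"fraction", "css", "clr"}
    #: batch-corrected CLR matrices are per-taxon affine images of CLR values
    #: and keep zero-sum only approximately; they set validate=False.
    validate: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mode not in ("fraction", "css", "clr"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.values.shape != (len(self.taxa), len(self.samples)):
            raise ValueError("values shape does not match taxa/samples")
        if not self.validate:
            return
        if self.mode == "fraction":
            col = self.values.sum(axis=0)
            if not np.allclose(col, 1.0, atol=1e-9):
                raise ValueError("fraction columns must sum to 1")
            if (self.values <= 0).any():
                raise ValueError("fractions must be strictly positive (run zero_replace)")
        elif self.mode == "clr":
            col = self.values.sum(axis=0)
            if not np.allclose(col, 0.0, atol=1e-7):
                raise ValueError("clr columns must sum to 0")

    def subset_samples(self, sample_ids: list[str]) -> "CompositionMatrix":
        idx = [self.samples.index(s) for s in sample_ids]
        return CompositionMatrix(
            list(self.taxa), list(sample_ids), self.values[:, idx], self.mode,
            self.validate,
        )


def zero_replace(counts: CountTable, delta: float = DEFAULT_DELTA) -> CompositionMatrix:
    """Close counts to strictly positive fractions with pseudo-count ``delta``.

    All-zero samples degenerate to the uniform composition (logged).
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    x = counts.counts.astype(float) + delta
    col = x.sum(axis=0)
    zero_cols = counts.counts.sum(axis=0) == 0
    if zero_cols.any():
        log.warning(
            "zero_replace: %d all-zero sample(s) mapped to uniform composition",
            int(zero_cols.sum()),
        )
    frac = x / col
    return CompositionMatrix(list(counts.taxa), list(counts.samples), frac, "fraction")


def css_scale(counts: CountTable, quantile: float = 0.5) -> CompositionMatrix:
    """Cumulative-sum scaling: divide each sample by the cumulative count sum
    up to its ``quantile``-th count value, then multiply by 1000.

    Scale-invariant per sample (doubling a sample's counts doubles the scale
    factor). All-zero samples are scaled by 1 and logged as degenerate.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    x = counts.counts.astype(float)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        positive = col[col > 0]
        if positive.size == 0:
            log.warning("css_scale: sample %s is all zeros; scaled by 1", counts.samples[j])
            out[:, j] = col * 1000.0
            continue
        threshold = np.quantile(positive, quantile)
        factor = col[col <= threshold].sum()
        if factor <= 0:  # defensive; cannot happen with a positive threshold
            factor = 1.0
        out[:, j] = col / factor * 1000.0
    return CompositionMatrix(list(counts.taxa), list(counts.samples), out, "css")


def clr_transform(comp: CompositionMatrix) -> CompositionMatrix:
    """Centered log-ratio: ln(x_i / g(x)) per sample; columns sum to zero."""
    if comp.mode != "fraction":
        raise ValueError("clr_transform expects fraction mode; run zero_replace first")
    if (comp.values <= 0).any():
        raise ValueError("clr_transform requires strictly positive fractions")
    logx = np.log(comp.values)
    clr = logx - logx.mean(axis=0, keepdims=True)
    return CompositionMatrix(list(comp.taxa), list(comp.samples), clr, "clr")
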