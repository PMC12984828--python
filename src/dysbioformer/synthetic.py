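"""Synthetic multi-study case-control microbiome cohorts.

Generates the inputs the pipeline assumes, with known ground truth, so every
downstream stage is testable without external downloads:

* a random coalescent-style binary tree with exponential branch lengths;
* per-sample latent log-abundances drawn from a multivariate normal whose
  covariance decays with patristic distance, exp(-d / corr_length), giving
  tree-correlated taxa;
* planted disease effects added (log-fold, latent scale) to case samples;
* per-study location/scale batch perturbations applied per taxon in log
  space (i.i.d. across taxa, so they survive the CLR's per-sample closure);
* softmax to a composition, then multinomial sampling at a log-normally
  overdispersed sequencing depth;
* optionally, reads with a Phred-dependent substitution error process
  (a base is resampled uniformly over the four nucleotides with probability
  exp(-alpha * Q), i.e. mismatch probability (3/4) exp(-alpha * Q)).

The generator is an acceptance oracle, not a claim about any real
collection: default study sizes mirror public gut case-control cohorts
(hundreds of samples per study) scaled down for desk-scale runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    CountTable,
    PhyloTree,
    ReadRecord,
    ReadSet,
    SampleMetadata,
    read_tree,
)

_BASES = np.array(list("ACGT"))

#: Mean branch length (substitutions/site-equivalents) for simulated trees.
TREE_BRANCH_MEAN = 0.1


@dataclass
class SimConfig:
    """Study conditions for a simulated multi-study case-control cohort."""

    n_taxa: int = 100
    #: (study_id, n_case, n_control) per study.
    studies: list[tuple[str, int, int]] = field(
        default_factory=lambda: [(f"study_{k + 1}", 40, 40) for k in range(5)]
    )
    #: taxon id -> planted log-fold effect (latent log scale) in cases.
    effect_taxa: dict[str, float] = field(default_factory=dict)
    batch_shift_sd: float = 0.5
    batch_scale_sd: float = 0.1
    sequencing_depth_mean: float = 20000.0
    overdispersion: float = 0.3  # log-normal sigma of per-sample depth
    corr_length: float = 1.0  # length scale of the tree covariance exp(-d/l)
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        ids = [s[0] for s in self.studies]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate study_id in studies")
        for name, value in (
            ("batch_shift_sd", self.batch_shift_sd),
            ("batch_scale_sd", self.batch_scale_sd),
            ("overdispersion", self.overdispersion),
        ):
            if value < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """Latent quantities the generator used; the oracle for recovery tests."""

    taxa: list[str]
    effects: np.ndarray  # per-taxon planted log-fold effect
    batch_location: dict[str, np.ndarray]  # per-study per-taxon shift
    batch_scale: dict[str, np.ndarray]  # per-study per-taxon scale factor
    depths: np.ndarray | None = None  # per-sample drawn sequencing depths

    @property
    def planted(self) -> list[str]:
        return [t for t, e in zip(self.taxa, self.effects) if e != 0.0]


def simulate_tree(n_taxa: int, seed: int) -> PhyloTree:
    """Random coalescent-style binary tree with Exp(mean 0.1) branch lengths."""
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    clades = [f"taxon_{i + 1:04d}" for i in range(n_taxa)]
    while len(clades) > 1:
        i, j = sorted(rng.choice(len(clades), size=2, replace=False))
        bl = rng.exponential(TREE_BRANCH_MEAN, size=2)
        merged = f"({clades[i]}:{bl[0]:.10f},{clades[j]}:{bl[1]:.10f})"
        clades = [c for k, c in enumerate(clades) if k not in (i, j)] + [merged]
    return read_tree(clades[0] + ";")


def simulate_cohorts(
    config: SimConfig, tree: PhyloTree
) -> tuple[CountTable, SampleMetadata, GroundTruth]:
    """Draw a multi-study cohort over the leading ``n_taxa`` leaves of ``tree``."""
    leaves = sorted(tree.leaf_labels)
    if len(leaves) < config.n_taxa:
        raise ValueError("tree has fewer leaves than n_taxa")
    taxa = leaves[: config.n_taxa]
    unknown = set(config.effect_taxa) - set(taxa)
    if unknown:
        raise ValueError(f"effect taxa not among simulated taxa: {sorted(unknown)[:5]}")

    _, d = tree.distance_matrix(taxa)
    cov = np.exp(-d / config.corr_length)
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(config.n_taxa))

    effects = np.array([config.effect_taxa.get(t, 0.0) for t in taxa])
    rng = np.random.default_rng(config.seed)

    batch_location: dict[str, np.ndarray] = {}
    batch_scale: dict[str, np.ndarray] = {}
    for study_id, _, _ in config.studies:
        batch_location[study_id] = rng.normal(0.0, config.batch_shift_sd, config.n_taxa)
        batch_scale[study_id] = np.exp(
            rng.normal(0.0, config.batch_scale_sd, config.n_taxa)
        )

    columns, sample_ids, labels, study_ids, depths = [], [], [], [], []
    mu_depth = math.log(config.sequencing_depth_mean) - config.overdispersion**2 / 2
    for study_id, n_case, n_control in config.studies:
        for k in range(n_case + n_control):
            is_case = k < n_case
            y = chol @ rng.standard_normal(config.n_taxa)
            if is_case:
                y = y + effects
            y = batch_location[study_id] + batch_scale[study_id] * y
            p = np.exp(y - y.max())
            p /= p.sum()
            depth = max(1, int(round(rng.lognormal(mu_depth, config.overdispersion))))
            columns.append(rng.multinomial(depth, p))
            depths.append(depth)
            sample_ids.append(f"{study_id}_s{k + 1:03d}")
            labels.append("disease" if is_case else "control")
            study_ids.append(study_id)

    counts = CountTable(taxa, sample_ids, np.column_stack(columns).astype(np.int64))
    frame = pd.DataFrame(
        {
            "study_id": study_ids,
            "label": labels,
            "age": np.round(rng.normal(35.7, 8.0, len(sample_ids)), 1),
            "bmi": np.round(rng.normal(24.2, 3.0, len(sample_ids)), 1),
            "sex": rng.choice(["M", "F"], len(sample_ids)),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = GroundTruth(taxa, effects, batch_location, batch_scale, np.array(depths))
    return counts, SampleMetadata(frame), truth


def simulate_reads(
    true_seqs: list[str],
    abundances,
    depth: int,
    error_alpha: float = math.log(10) / 10,
    seed: int = 0,
    quality_mean: float = 30.0,
    quality_sd: float = 5.0,
) -> tuple[ReadSet, np.ndarray]:
    """Sample ``depth`` reads from ``true_seqs`` with Phred-dependent errors.

    Per base, Phred Q is a clipped rounded normal (quality profile); the base
    is resampled uniformly over {A,C,G,T} with probability exp(-alpha * Q),
    so the expected mismatch rate is (3/4) * exp(-alpha * Q). Returns the
    reads and the per-read true source index (the denoising oracle).
    """
    if not true_seqs:
        raise ValueError("true_seqs must be non-empty")
    if error_alpha <= 0:
        raise ValueError("error_alpha must be > 0")
    abundances = np.asarray(abundances, dtype=float)
    if abs(abundances.sum() - 1.0) > 1e-9:
        raise ValueError("abundances must sum to 1")
    rng = np.random.default_rng(seed)
    sources = rng.choice(len(true_seqs), size=depth, p=abundances)
    records = []
    for r, src in enumerate(sources):
        seq = np.array(list(true_seqs[src]))
        L = len(seq)
        q = np.clip(np.round(rng.normal(quality_mean, quality_sd, L)), 0, 41).astype(int)
        flip = rng.random(L) < np.exp(-error_alpha * q)
        if flip.any():
            seq = seq.copy()
            seq[flip] = _BASES[rng.integers(0, 4, int(flip.sum()))]
        records.append(ReadRecord(f"read_{r + 1:06d}", "".join(seq), q))
    return ReadSet(records), sources


def random_sequences(n: int, length: int, seed: int, min_hamming: int = 0) -> list[str]:
    """Random DNA sequences, optionally re-drawn until pairwise Hamming
    distance >= ``min_hamming`` (all equal length)."""
    rng = np.random.default_rng(seed)
    seqs: list[str] = []
    while len(seqs) < n:
        cand = "".join(rng.choice(_BASES, length))
        if all(
            sum(a != b for a, b in zip(cand, s)) >= min_hamming for s in seqs
        ):
            seqs.append(cand)
    return seqs
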