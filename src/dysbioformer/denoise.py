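"""Quality filtering, error-model denoising to ASVs, and chimera removal.

The error model ties the per-base error probability to the Phred score as
P_err(Q) = exp(-alpha * Q); with alpha = ln(10)/10 this coincides with the
standard Phred definition 10^(-Q/10). Reads whose expected error count
sum_i exp(-alpha * Q_i) exceeds a threshold are discarded. The denoiser is a
greedy abundance-ranked partitioner in the DADA family: unique sequences are
visited in decreasing abundance; each is either absorbed into the existing
center under which its reads are plausibly error copies, or promoted to a
new center when its abundance is implausibly high under the best center's
substitution model (binomial tail test). Substitutions only — no indels —
so sequences of different lengths never merge.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from .io_formats import ReadSet

log = logging.getLogger(__name__)

#: alpha = ln(10)/10 makes P_err(Q) equal the Phred probability 10^(-Q/10).
PHRED_ALPHA = math.log(10) / 10.0
DEFAULT_MAX_EE = 2.0
#: Abundance p-value below which a sequence becomes its own center.
DEFAULT_OMEGA = 1e-6


@dataclass
class ErrorModel:
    alpha: float = PHRED_ALPHA
    max_expected_errors: float = DEFAULT_MAX_EE

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.max_expected_errors <= 0:
            raise ValueError("max_expected_errors must be > 0")


def error_probability(q, alpha: float = PHRED_ALPHA):
    """P_err(Q) = exp(-alpha * Q); scalar or array, Q >= 0 required."""
    q = np.asarray(q, dtype=float)
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if (q < 0).any():
        raise ValueError("Phred scores must be >= 0")
    out = np.exp(-alpha * q)
    return float(out) if out.ndim == 0 else out


def expected_errors(quality: np.ndarray, alpha: float = PHRED_ALPHA) -> float:
    """Expected number of erroneous bases in a read: sum_i exp(-alpha Q_i)."""
    return float(error_probability(np.asarray(quality), alpha).sum())


def filter_reads(reads: ReadSet, model: ErrorModel) -> tuple[ReadSet, float]:
    """Keep reads with expected errors <= model.max_expected_errors.

    Returns the retained reads and the retention fraction.
    """
    kept = [
        r
        for r in reads
        if expected_errors(r.quality, model.alpha) <= model.max_expected_errors
    ]
    fraction = len(kept) / len(reads) if len(reads) else 1.0
    log.info("filter_reads: retained %d/%d reads (%.1f%%)", len(kept), len(reads), 100 * fraction)
    return ReadSet(kept), fraction


@dataclass
class ASVTable:
    """Denoised amplicon sequence variants with read provenance."""

    sequences: list[str]
    counts: np.ndarray  # reads assigned per ASV
    provenance: list[list[str]] = field(default_factory=list)  # read ids per ASV

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != len(self.sequences):
            raise ValueError("counts length must match sequences")
        if self.provenance and len(self.provenance) != len(self.sequences):
            raise ValueError("provenance length must match sequences")

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())


class _Unique:
    __slots__ = ("seq", "read_ids", "mean_q")

    def __init__(self, seq: str, read_ids: list[str], mean_q: np.ndarray):
        self.seq = seq
        self.read_ids = read_ids
        self.mean_q = mean_q  # per-position mean observed Phred score


def _read_likelihood(candidate: _Unique, center_seq: str, alpha: float) -> float:
    """log P(candidate sequence | center, error model).

    Mismatching positions contribute log(P_err/3) (a substitution to one
    specific alternative), matching positions log(1 - P_err), with P_err
    evaluated at the candidate's observed per-position mean quality.
    """
    p = np.exp(-alpha * candidate.mean_q)
    mismatch = np.fromiter(
        (a != b for a, b in zip(candidate.seq, center_seq)), dtype=bool
    )
    with np.errstate(divide="ignore"):
        ll = np.where(mismatch, np.log(p / 3.0), np.log1p(-p)).sum()
    return float(ll)


def denoise_reads(
    reads: ReadSet, model: ErrorModel, omega: float = DEFAULT_OMEGA
) -> ASVTable:
    """Greedy abundance-ranked partitioning of reads into ASVs.

    Unique sequences are sorted by (abundance desc, sequence asc). The most
    abundant becomes the first center. Each subsequent unique sequence is
    scored against every same-length center; if the binomial tail probability
    of seeing its abundance as error copies of the best center — conditioned
    on it being observed at all — is <= omega it is promoted to a new center,
    otherwise its reads are absorbed. Singletons therefore never seed new
    centers. Read counts are conserved exactly.
    """
    if len(reads) == 0:
        return ASVTable([], np.zeros(0, dtype=np.int64), [])

    by_seq: dict[str, list] = {}
    for r in reads:
        by_seq.setdefault(r.sequence, []).append(r)
    uniques = []
    for seq, members in by_seq.items():
        mean_q = np.mean([m.quality for m in members], axis=0)
        uniques.append(_Unique(seq, [m.read_id for m in members], mean_q))
    uniques.sort(key=lambda u: (-len(u.read_ids), u.seq))

    centers: list[_Unique] = []
    assigned: list[list[str]] = []
    for u in uniques:
        if not centers:
            centers.append(u)
            assigned.append(list(u.read_ids))
            continue
        best_idx, best_ll = -1, -np.inf
        for c_idx, c in enumerate(centers):
            if len(c.seq) != len(u.seq):
                continue
            ll = _read_likelihood(u, c.seq, model.alpha)
            if best_idx < 0:
                better = True
            elif ll != best_ll:
                better = ll > best_ll
            else:
                # tie-break toward the more abundant center, then the
                # lexicographically smaller sequence
                n_c, n_b = len(assigned[c_idx]), len(assigned[best_idx])
                better = n_c > n_b or (n_c == n_b and c.seq < centers[best_idx].seq)
            if better:
                best_idx, best_ll = c_idx, ll
        if best_idx < 0:
            centers.append(u)
            assigned.append(list(u.read_ids))
            continue
        n_center = len(assigned[best_idx])
        p_err = math.exp(best_ll) if best_ll > -700 else 0.0
        abundance = len(u.read_ids)
        # abundance p-value conditioned on being observed at all: a singleton
        # can never be implausibly abundant, so it never seeds a new center
        if abundance <= 1:
            pval = 1.0
        else:
            sf0 = float(binom.sf(0, n_center, min(1.0, p_err)))
            if sf0 <= 0.0:
                pval = 0.0  # even one error copy is essentially impossible
            else:
                pval = float(binom.sf(abundance - 1, n_center, min(1.0, p_err))) / sf0
        if pval <= omega:
            centers.append(u)
            assigned.append(list(u.read_ids))
        else:
            assigned[best_idx].extend(u.read_ids)

    order = sorted(
        range(len(centers)), key=lambda i: (-len(assigned[i]), centers[i].seq)
    )
    table = ASVTable(
        [centers[i].seq for i in order],
        np.array([len(assigned[i]) for i in order], dtype=np.int64),
        [assigned[i] for i in order],
    )
    assert table.total_reads == len(reads), "read-count conservation violated"
    return table


def remove_chimeras(
    asvs: ASVTable, min_parent_fold: float = 2.0, min_gain: float = 0.02
) -> ASVTable:
    """Flag and remove two-parent splice artifacts.

    An ASV is chimeric when some split point k yields a left segment matching
    one parent and a right segment matching a *different* parent — both at
    least ``min_parent_fold`` times more abundant — with a combined identity
    exceeding the ASV's best single-parent identity by >= ``min_gain``.
    """
    n = len(asvs.sequences)
    keep = np.ones(n, dtype=bool)
    for i, seq in enumerate(asvs.sequences):
        L = len(seq)
        parents = [
            j
            for j in range(n)
            if j != i
            and len(asvs.sequences[j]) == L
            and asvs.counts[j] >= min_parent_fold * asvs.counts[i]
        ]
        if len(parents) < 2:
            continue
        matches = {
            j: np.fromiter(
                (a == b for a, b in zip(seq, asvs.sequences[j])), dtype=float
            )
            for j in parents
        }
        best_single = max(matches[j].mean() for j in parents)
        prefix = {j: np.concatenate(([0.0], np.cumsum(matches[j]))) for j in parents}
        best_chimera = 0.0
        for k in range(1, L):
            left = max(prefix[j][k] for j in parents)
            # best right parent must differ from the best left parent
            left_j = max(parents, key=lambda j: prefix[j][k])
            right_candidates = [
                (prefix[j][L] - prefix[j][k], j) for j in parents if j != left_j
            ]
            if not right_candidates:
                continue
            right, _ = max(right_candidates)
            best_chimera = max(best_chimera, (left + right) / L)
        if best_chimera - best_single >= min_gain:
            keep[i] = False
            log.info(
                "remove_chimeras: flagged ASV %d (identity gain %.3f)",
                i,
                best_chimera - best_single,
            )
    idx = np.where(keep)[0]
    return ASVTable(
        [asvs.sequences[i] for i in idx],
        asvs.counts[idx],
        [asvs.provenance[i] for i in idx] if asvs.provenance else [],
    )
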