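"""Readers and writers for the standard formats the pipeline touches.

Count tables and sample metadata travel as dense TSV, trees as Newick with
branch lengths, reads as Phred+33 FASTQ. All readers validate on entry and
raise :class:`FormatError` (malformed file) or :class:`ValidationError`
(well-formed file violating a domain invariant) with messages that name the
offending record.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """The file could not be parsed as the expected format."""


class ValidationError(ValueError):
    """The file parsed but violates a domain invariant."""


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

@dataclass
class CountTable:
    """Taxon-by-sample matrix of non-negative integer counts.

    ``counts`` has shape ``(len(taxa), len(samples))``; row/column order is
    meaningful and preserved through IO round-trips.
    """

    taxa: list[str]
    samples: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(set(self.taxa)) != len(self.taxa):
            raise ValidationError("duplicate taxon IDs in count table")
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample IDs in count table")
        if self.counts.shape != (len(self.taxa), len(self.samples)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"({len(self.taxa)}, {len(self.samples)})"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValidationError("counts must be integers")
        if (self.counts < 0).any():
            t, s = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count for taxon {self.taxa[t]!r}, sample {self.samples[s]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.samples.index(sample_id)]

    def subset_samples(self, sample_ids: list[str]) -> "CountTable":
        idx = [self.samples.index(s) for s in sample_ids]
        return CountTable(list(self.taxa), list(sample_ids), self.counts[:, idx])


def read_count_table(path) -> CountTable:
    """Read a dense TSV count table (rows = taxa, columns = samples)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise FormatError(f"could not parse count table {path}: {exc}") from exc
    if df.empty and df.shape[1] == 0:
        raise FormatError(f"count table {path} has no sample columns")
    taxa = [str(t) for t in df.index]
    samples = [str(s) for s in df.columns]
    counts = np.empty(df.shape, dtype=np.int64)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            try:
                value = int(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-integer cell {cell!r} for taxon {taxa[i]!r}, "
                    f"sample {samples[j]!r}"
                ) from None
            if value < 0:
                raise ValidationError(
                    f"negative count {value} for taxon {taxa[i]!r}, "
                    f"sample {samples[j]!r}"
                )
            counts[i, j] = value
    return CountTable(taxa, samples, counts)


def write_count_table(table: CountTable, path) -> None:
    df = pd.DataFrame(table.counts, index=table.taxa, columns=table.samples)
    df.index.name = "taxon_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

_MANDATORY_META = ("sample_id", "study_id", "label")
_OPTIONAL_META = ("age", "bmi", "sex")


@dataclass
class SampleMetadata:
    """Per-sample clinical/batch metadata.

    ``frame`` is indexed by sample_id with columns ``study_id``, ``label`` and
    optionally ``age`` (years), ``bmi`` (kg/m^2), ``sex``. Missing optional
    values stay as NaN/None; nothing is imputed at this layer.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            dup = self.frame.index[self.frame.index.duplicated()][0]
            raise ValidationError(f"duplicate sample_id {dup!r} in metadata")
        for col in ("study_id", "label"):
            if col not in self.frame.columns:
                raise FormatError(f"metadata is missing mandatory column {col!r}")
            bad = self.frame[col].isna() | (self.frame[col].astype(str) == "")
            if bad.any():
                sid = self.frame.index[bad][0]
                raise ValidationError(f"empty {col!r} for sample {sid!r}")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.frame.index]

    @property
    def label_set(self) -> list[str]:
        return sorted(self.frame["label"].astype(str).unique())

    def label_histogram(self) -> dict[str, int]:
        return self.frame["label"].astype(str).value_counts().to_dict()

    def labels(self, sample_ids=None) -> np.ndarray:
        if sample_ids is None:
            return self.frame["label"].astype(str).to_numpy()
        return self.frame.loc[list(sample_ids), "label"].astype(str).to_numpy()

    def studies(self, sample_ids=None) -> np.ndarray:
        if sample_ids is None:
            return self.frame["study_id"].astype(str).to_numpy()
        return self.frame.loc[list(sample_ids), "study_id"].astype(str).to_numpy()

    def subset(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[list(sample_ids)].copy())


def read_metadata(path) -> SampleMetadata:
    """Read a TSV with columns sample_id, study_id, label (+ optional age/bmi/sex)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover
        raise FormatError(f"could not parse metadata {path}: {exc}") from exc
    for col in _MANDATORY_META:
        if col not in df.columns:
            raise FormatError(f"metadata {path} is missing mandatory column {col!r}")
    df = df.set_index("sample_id")
    for col in ("age", "bmi"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    out = meta.frame.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def check_sample_overlap(counts: CountTable, meta: SampleMetadata) -> dict[str, set[str]]:
    """Join check: samples present in one input but absent from the other."""
    c, m = set(counts.samples), set(meta.sample_ids)
    return {"counts_only": c - m, "metadata_only": m - c}


# ---------------------------------------------------------------------------
# Reads (FASTQ, Phred+33)
# ---------------------------------------------------------------------------

@dataclass
class ReadRecord:
    read_id: str
    sequence: str
    quality: np.ndarray  # integer Phred scores, one per base

    def __post_init__(self) -> None:
        self.quality = np.asarray(self.quality, dtype=np.int64)
        if len(self.sequence) != len(self.quality):
            raise ValidationError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.quality)}"
            )
        if (self.quality < 0).any():
            raise ValidationError(f"read {self.read_id!r}: negative Phred score")


@dataclass
class ReadSet:
    records: list[ReadRecord]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def read_fastq(path) -> ReadSet:
    """Read Phred+33 FASTQ ('!' -> Q0, 'I' -> Q40)."""
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            q = np.asarray(rec.letter_annotations["phred_quality"], dtype=np.int64)
            records.append(ReadRecord(rec.id, str(rec.seq), q))
    except ValueError as exc:
        raise FormatError(f"could not parse FASTQ {path}: {exc}") from exc
    return ReadSet(records)


def write_fastq(reads: ReadSet, path) -> None:
    recs = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in r.quality]
        recs.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fastq")


# ---------------------------------------------------------------------------
# Phylogenetic trees (Newick)
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    """Rooted tree with taxon-labelled leaves and non-negative branch lengths."""

    tree: dendropy.Tree = field(repr=False)

    def __post_init__(self) -> None:
        labels = self.leaf_labels
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate leaf labels in tree")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValidationError(f"negative branch length {edge.length}")

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter() if lf.taxon]

    def distance_matrix(self, taxa: list[str] | None = None) -> tuple[list[str], np.ndarray]:
        """Pairwise patristic distances (sum of branch lengths on the path)."""
        pdm = self.tree.phylogenetic_distance_matrix()
        by_label = {t.label: t for t in self.tree.taxon_namespace}
        if taxa is None:
            taxa = self.leaf_labels
        missing = [t for t in taxa if t not in by_label]
        if missing:
            raise ValidationError(f"taxa missing from tree: {missing[:5]}")
        n = len(taxa)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pdm.patristic_distance(
                    by_label[taxa[i]], by_label[taxa[j]]
                )
        return list(taxa), d

    def as_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()


def read_tree(source) -> PhyloTree:
    """Parse a Newick tree from a path or a raw Newick string."""
    text = None
    if isinstance(source, str) and source.lstrip().startswith("("):
        text = source
    else:
        with open(source) as fh:
            text = fh.read()
    try:
        tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    except Exception as exc:
        raise FormatError(f"could not parse Newick: {exc}") from exc
    return PhyloTree(tree)


def write_tree(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_newick() + "\n")
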