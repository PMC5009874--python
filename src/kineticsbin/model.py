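"""Core domain types and file I/O.

Expression is handled at two levels: isoform-level FPKM tables (the unit the
quantifier emits) and gene-level tables obtained by summing a gene's
constituent isoforms.  Transcript structures come from GTF annotations and
are stored with 0-based half-open exon coordinates so that length arithmetic
(junction flanks in particular) is unambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "Thresholds",
    "ExpressionMatrix",
    "GeneExpressionMatrix",
    "LibraryStats",
    "TranscriptModel",
    "read_isoform_fpkm",
    "write_isoform_fpkm",
    "read_gene_fpkm",
    "write_gene_fpkm",
    "read_library_stats",
    "write_library_stats",
    "aggregate_genes",
    "read_gtf",
    "write_gtf",
]


class ValidationError(ValueError):
    """An input violated a type invariant (bad file, bad value, bad call)."""


@dataclass(frozen=True)
class Thresholds:
    """Pipeline-wide decision thresholds.

    Attributes
    ----------
    expression_fpkm : float
        A gene (or isoform) with FPKM >= this value counts as expressed;
        ties at the threshold are expressed. Default 1.0 FPKM.
    fold : float
        Minimum fold change (inclusive) for an over-representation call.
    fisher_alpha : float
        Significance level for the exact test (raw p, no correction).
    benjamini_alpha : float
        Benjamini-Hochberg q-value cutoff for term enrichment.
    min_flank : int
        Minimum exon length (bases) on each side of a junction for a probe
        to be kept; flanks of 12 bases or fewer are eliminated.
    """

    expression_fpkm: float = 1.0
    fold: float = 2.0
    fisher_alpha: float = 0.01
    benjamini_alpha: float = 0.05
    min_flank: int = 13

    def __post_init__(self) -> None:
        for name in ("expression_fpkm", "fold", "fisher_alpha", "benjamini_alpha"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"Thresholds.{name} must be strictly positive")
        if self.min_flank < 1:
            raise ValidationError("Thresholds.min_flank must be >= 1")


@dataclass
class LibraryStats:
    """Per-sample sequencing depth: the number of mapped fragments."""

    sample: str
    mapped_fragments: int

    def __post_init__(self) -> None:
        if self.mapped_fragments < 1:
            raise ValidationError(
                f"mapped_fragments for sample {self.sample!r} must be >= 1"
            )


@dataclass
class ExpressionMatrix:
    """Isoform-by-sample FPKM values with an isoform-to-gene mapping.

    ``fpkm`` is a DataFrame indexed by isoform id with one column per sample;
    ``gene_of_isoform`` is a Series aligned to the same index.
    """

    fpkm: pd.DataFrame
    gene_of_isoform: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.fpkm.index.has_duplicates:
            dups = self.fpkm.index[self.fpkm.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate isoform ids: {dups}")
        if len(set(self.fpkm.columns)) != len(self.fpkm.columns):
            raise ValidationError("sample names must be unique")
        if not self.gene_of_isoform.index.equals(self.fpkm.index):
            raise ValidationError("gene_of_isoform index must match fpkm index")
        values = self.fpkm.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("FPKM values must be numeric")
        bad = ~np.isfinite(values) | (values < 0)
        if bad.any():
            rows = self.fpkm.index[bad.any(axis=1)].tolist()
            raise ValidationError(
                f"negative, missing or non-finite FPKM in isoform rows: {rows}"
            )

    @property
    def isoform_ids(self) -> list[str]:
        return self.fpkm.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.fpkm.columns.tolist()

    def isoforms_of_gene(self, gene_id: str) -> list[str]:
        return self.gene_of_isoform.index[self.gene_of_isoform == gene_id].tolist()


@dataclass
class GeneExpressionMatrix:
    """Gene-by-sample FPKM values (sum over each gene's isoforms)."""

    fpkm: pd.DataFrame

    def __post_init__(self) -> None:
        if self.fpkm.index.has_duplicates:
            dups = self.fpkm.index[self.fpkm.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups}")
        values = self.fpkm.to_numpy()
        if (~np.isfinite(values) | (values < 0)).any():
            raise ValidationError("gene FPKM values must be finite and >= 0")

    @property
    def gene_ids(self) -> list[str]:
        return self.fpkm.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.fpkm.columns.tolist()


@dataclass
class TranscriptModel:
    """A transcript as an ordered list of exons on one strand.

    Exon coordinates are 0-based half-open genomic intervals, sorted in
    genomic order and non-overlapping.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(
                f"transcript {self.transcript_id!r}: strand must be '+' or '-'"
            )
        prev_end = None
        for start, end in self.exons:
            if end - start < 1:
                raise ValidationError(
                    f"transcript {self.transcript_id!r}: exon [{start},{end}) "
                    "has length < 1"
                )
            if prev_end is not None and start < prev_end:
                raise ValidationError(
                    f"transcript {self.transcript_id!r}: exons overlap or are "
                    "unsorted"
                )
            prev_end = end

    @property
    def n_exons(self) -> int:
        return len(self.exons)


# ---------------------------------------------------------------------------
# TSV expression tables
# ---------------------------------------------------------------------------

_ISOFORM_KEY_COLS = ["isoform_id", "gene_id"]


def read_isoform_fpkm(path: str | Path) -> ExpressionMatrix:
    """Read an isoform-level FPKM table.

    The file is tab-delimited with a header row: ``isoform_id``, ``gene_id``,
    then one column per sample.  Rows violating invariants (duplicate
    isoform id, negative or non-numeric FPKM) are rejected with a message
    naming the offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    missing = [c for c in _ISOFORM_KEY_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    sample_cols = [c for c in df.columns if c not in _ISOFORM_KEY_COLS]
    if not sample_cols:
        raise ValidationError(f"{path}: no sample columns found")
    for col in sample_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | ~np.isfinite(numeric) | (numeric < 0)
        if bad.any():
            row = df.loc[bad.idxmax()]
            raise ValidationError(
                f"{path}: invalid FPKM {row[col]!r} for isoform "
                f"{row['isoform_id']!r} in sample {col!r}"
            )
        df[col] = numeric.astype(float)
    if df["isoform_id"].duplicated().any():
        dup = df.loc[df["isoform_id"].duplicated(), "isoform_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate isoform id {dup!r}")
    fpkm = df.set_index("isoform_id")[sample_cols]
    genes = df.set_index("isoform_id")["gene_id"]
    matrix = ExpressionMatrix(fpkm=fpkm, gene_of_isoform=genes)
    logger.info("read %d isoforms x %d samples from %s", *fpkm.shape, path)
    return matrix


def write_isoform_fpkm(x: ExpressionMatrix, path: str | Path) -> None:
    out = x.fpkm.copy()
    out.insert(0, "gene_id", x.gene_of_isoform)
    out.to_csv(path, sep="\t", index_label="isoform_id")


def read_gene_fpkm(path: str | Path) -> GeneExpressionMatrix:
    """Read a gene-level FPKM table (columns ``gene_id`` then samples)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if "gene_id" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'gene_id'")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate gene id {dup!r}")
    return GeneExpressionMatrix(fpkm=df.set_index("gene_id").astype(float))


def write_gene_fpkm(x: GeneExpressionMatrix, path: str | Path) -> None:
    x.fpkm.to_csv(path, sep="\t", index_label="gene_id")


def read_library_stats(path: str | Path) -> dict[str, LibraryStats]:
    """Read per-sample mapped-fragment counts (columns sample, mapped_fragments)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    for col in ("sample", "mapped_fragments"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    if df["sample"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample names")
    return {
        row["sample"]: LibraryStats(row["sample"], int(row["mapped_fragments"]))
        for _, row in df.iterrows()
    }


def write_library_stats(libs: Mapping[str, LibraryStats], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample": list(libs),
            "mapped_fragments": [libs[s].mapped_fragments for s in libs],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene aggregation
# ---------------------------------------------------------------------------


def aggregate_genes(x: ExpressionMatrix) -> GeneExpressionMatrix:
    """Sum isoform FPKMs per gene.

    Gene expression is defined as the sum of FPKM of a gene's constituent
    isoforms; genes appear in order of first appearance of their isoforms.
    """
    summed = x.fpkm.groupby(x.gene_of_isoform, sort=False).sum()
    summed.index.name = "gene_id"
    return GeneExpressionMatrix(fpkm=summed)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Parse exon features from a GTF file into transcript models.

    GTF coordinates are 1-based inclusive; they are converted to 0-based
    half-open at this boundary.  Exons must carry ``gene_id`` and
    ``transcript_id`` attributes.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise ValidationError(f"{path}: malformed GTF ({exc})") from exc

    by_tx: dict[str, TranscriptModel] = {}
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        try:
            tx_id = feat.attributes["transcript_id"][0]
            gene_id = feat.attributes["gene_id"][0]
        except KeyError as exc:
            raise ValidationError(
                f"{path}: exon at {feat.seqid}:{feat.start}-{feat.end} lacks "
                f"attribute {exc}"
            ) from exc
        exon = (feat.start - 1, feat.end)  # to 0-based half-open
        model = by_tx.get(tx_id)
        if model is None:
            by_tx[tx_id] = TranscriptModel(
                transcript_id=tx_id,
                gene_id=gene_id,
                chrom=feat.seqid,
                strand=feat.strand,
                exons=[exon],
            )
        else:
            model.exons.append(exon)

    transcripts = []
    for model in by_tx.values():
        model.exons.sort()
        transcripts.append(
            TranscriptModel(
                transcript_id=model.transcript_id,
                gene_id=model.gene_id,
                chrom=model.chrom,
                strand=model.strand,
                exons=model.exons,
            )
        )
    logger.info("read %d transcripts from %s", len(transcripts), path)
    return transcripts


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcripts as GTF exon lines (1-based inclusive on output)."""
    with open(path, "w") as fh:
        for tx in transcripts:
            for start, end in tx.exons:
                attrs = (
                    f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
                )
                fh.write(
                    f"{tx.chrom}\tkineticsbin\texon\t{start + 1}\t{end}\t.\t"
                    f"{tx.strand}\t.\t{attrs}\n"
                )
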