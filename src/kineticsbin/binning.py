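"""Expression binning for a two-sample comparison.

Every gene of the comparison universe lands in exactly one bin:

* ``No_Ex`` — below the expression threshold in both samples;
* ``A_Only`` / ``B_Only`` — expressed in exactly one sample (rendered with
  the sample's name, e.g. ``P0NE_Only``);
* ``OR_A`` / ``OR_B`` — expressed in both and called over-represented by
  the consensus DE rule;
* ``Non_DR`` — expressed in both with no consensus call.

Expressed (gene, sample) pairs additionally carry an alternative-splicing
sub-category: SI (single annotated isoform), MI (two or more isoforms above
threshold), MOAT (multiple isoforms, exactly one above threshold) or MIBT
(multiple isoforms all individually below threshold whose sum is above it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import de as _de
from .model import (
    ExpressionMatrix,
    GeneExpressionMatrix,
    Thresholds,
    ValidationError,
    aggregate_genes,
)

logger = logging.getLogger(__name__)

# canonical bin labels (A/B abstract over the two sample names)
NO_EX = "No_Ex"
A_ONLY = "A_Only"
B_ONLY = "B_Only"
OR_A = "OR_A"
OR_B = "OR_B"
NON_DR = "Non_DR"
BIN_LABELS = (NO_EX, A_ONLY, B_ONLY, OR_A, OR_B, NON_DR)

# splice categories
SI = "SI"
MI = "MI"
MOAT = "MOAT"
MIBT = "MIBT"
SPLICE_CATEGORIES = (SI, MI, MOAT, MIBT)

_SWAP = {NO_EX: NO_EX, A_ONLY: B_ONLY, B_ONLY: A_ONLY, OR_A: OR_B, OR_B: OR_A, NON_DR: NON_DR}


def swap_bin(bin_label: str) -> str:
    """Canonical bin under a swap of the two samples."""
    return _SWAP[bin_label]


def render_bin(bin_label: str, sample_a: str, sample_b: str) -> str:
    """Render a canonical bin with the comparison's sample names."""
    return {
        NO_EX: NO_EX,
        NON_DR: NON_DR,
        A_ONLY: f"{sample_a}_Only",
        B_ONLY: f"{sample_b}_Only",
        OR_A: f"OR_{sample_a}",
        OR_B: f"OR_{sample_b}",
    }[bin_label]


def classify_expression(
    fpkm_A: float, fpkm_B: float, t: Thresholds = Thresholds()
) -> str:
    """Coarse expression class: No_Ex, A_Only, B_Only or Both.

    The threshold is inclusive: FPKM exactly at the threshold counts as
    expressed.
    """
    a = fpkm_A >= t.expression_fpkm
    b = fpkm_B >= t.expression_fpkm
    if a and b:
        return "Both"
    if a:
        return A_ONLY
    if b:
        return B_ONLY
    return NO_EX


def splice_category(
    isoform_fpkms: Sequence[float], t: Thresholds = Thresholds()
) -> str:
    """Alternative-splicing category of an expressed (gene, sample) pair.

    SI for a single annotated isoform; otherwise MIBT when every isoform is
    individually below threshold, MOAT when exactly one is at/above it, MI
    when two or more are.  The isoform-level threshold equals the gene-level
    expression threshold.
    """
    values = list(isoform_fpkms)
    if not values:
        raise ValidationError("splice_category requires at least one isoform")
    if sum(values) < t.expression_fpkm:
        raise ValidationError(
            "splice_category called on a non-expressed (gene, sample) pair"
        )
    if len(values) == 1:
        return SI
    n_above = sum(v >= t.expression_fpkm for v in values)
    if n_above == 0:
        return MIBT
    if n_above == 1:
        return MOAT
    return MI


@dataclass
class BinningResult:
    """Bin assignments for one comparison.

    ``table`` is indexed by gene id with columns: ``bin`` (canonical),
    ``bin_label`` (rendered with sample names), ``fpkm_A``, ``fpkm_B``,
    ``splice_A``, ``splice_B`` (None for non-expressed pairs), ``fold``,
    ``fisher_p``, ``external_call``, ``defining_sample``.
    """

    table: pd.DataFrame
    sample_a: str
    sample_b: str
    thresholds: Thresholds

    def bins(self) -> pd.Series:
        """Canonical bin per gene."""
        return self.table["bin"]

    def rendered_bins(self) -> pd.Series:
        return self.table["bin_label"]

    def genes_in_bin(self, bin_label: str) -> list[str]:
        """Genes in a bin, by canonical or rendered label."""
        mask = (self.table["bin"] == bin_label) | (self.table["bin_label"] == bin_label)
        return self.table.index[mask].tolist()

    def counts(self) -> pd.Series:
        return self.table["bin"].value_counts().reindex(BIN_LABELS, fill_value=0)

    def summary(self) -> pd.DataFrame:
        """Per-bin gene counts and alternatively-spliced fractions.

        The alternatively-spliced fraction of a bin is the fraction of its
        genes whose splice category in the bin's defining sample is MI
        (two or more isoforms above threshold).  No_Ex genes have no
        defining sample, so their fraction is NaN.
        """
        rows = []
        for b in BIN_LABELS:
            sub = self.table[self.table["bin"] == b]
            n = len(sub)
            if b == NO_EX or n == 0:
                frac = float("nan")
            else:
                cats = [
                    row["splice_A"] if row["defining_sample"] == self.sample_a else row["splice_B"]
                    for _, row in sub.iterrows()
                ]
                frac = sum(c == MI for c in cats) / n
            rows.append(
                {
                    "bin": render_bin(b, self.sample_a, self.sample_b),
                    "n_genes": n,
                    "fraction_alternatively_spliced": frac,
                }
            )
        return pd.DataFrame(rows)

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


def bin_comparison(
    isoforms: ExpressionMatrix,
    sample_a: str,
    sample_b: str,
    libs: Mapping[str, "_de.LibraryStats"] | None = None,
    external: Mapping[str, str] | None = None,
    housekeeping: str = "Gapdh",
    thresholds: Thresholds = Thresholds(),
    gene_universe: Sequence[str] | None = None,
    de_results: Mapping[str, "_de.DEResult"] | None = None,
) -> BinningResult:
    """Bin every gene of a two-sample comparison.

    DE evidence for genes expressed in both samples is either supplied
    pre-computed (``de_results``) or computed here from library sizes and
    optional external calls.  ``gene_universe`` extends the universe beyond
    the FPKM table: listed genes absent from the table are treated as FPKM 0
    in both samples (they land in No_Ex), so the No_Ex bin can reflect an
    annotation-wide gene list.
    """
    t = thresholds
    if sample_a not in isoforms.samples or sample_b not in isoforms.samples:
        raise ValidationError(
            f"samples {sample_a!r}, {sample_b!r} must both be in the matrix "
            f"(has {isoforms.samples})"
        )
    genes = aggregate_genes(isoforms)
    fa = genes.fpkm[sample_a].astype(float)
    fb = genes.fpkm[sample_b].astype(float)

    universe = list(genes.gene_ids)
    if gene_universe is not None:
        known = set(universe)
        extra = [g for g in gene_universe if g not in known]
        universe = universe + extra
        fa = fa.reindex(universe, fill_value=0.0)
        fb = fb.reindex(universe, fill_value=0.0)

    if de_results is None:
        need_de = [
            g
            for g in universe
            if fa.at[g] >= t.expression_fpkm and fb.at[g] >= t.expression_fpkm
        ]
        if need_de:
            if libs is None:
                raise ValidationError(
                    "library stats are required to compute DE for genes "
                    "expressed in both samples"
                )
            de_results = _de.run_de(
                genes, sample_a, sample_b, libs, external, housekeeping, t
            )
    de_results = de_results or {}

    # per-(gene, sample) splice categories for expressed pairs
    iso_by_gene: dict[str, list[str]] = {}
    for iso, gene in isoforms.gene_of_isoform.items():
        iso_by_gene.setdefault(gene, []).append(iso)

    records = []
    for gene in universe:
        a, b = float(fa.at[gene]), float(fb.at[gene])
        cls = classify_expression(a, b, t)
        fold = np.nan
        fisher_p = np.nan
        call = None
        if cls == "Both":
            if gene not in de_results:
                raise ValidationError(
                    f"gene {gene!r} is expressed in both samples but has no "
                    "DE result"
                )
            r = de_results[gene]
            status = r.status
            bin_label = {_de.OR_A: OR_A, _de.OR_B: OR_B, _de.NON_DR: NON_DR}[status]
            fold, fisher_p, call = r.fold, r.fisher_p, r.external_call
        else:
            bin_label = cls

        isos = iso_by_gene.get(gene, [])
        splice_a = splice_b = None
        if isos:
            if a >= t.expression_fpkm:
                splice_a = splice_category(
                    isoforms.fpkm.loc[isos, sample_a].tolist(), t
                )
            if b >= t.expression_fpkm:
                splice_b = splice_category(
                    isoforms.fpkm.loc[isos, sample_b].tolist(), t
                )

        # defining sample for the per-bin splice summary
        if bin_label in (A_ONLY, OR_A):
            defining = sample_a
        elif bin_label in (B_ONLY, OR_B):
            defining = sample_b
        elif bin_label == NON_DR:
            defining = sample_a if a >= b else sample_b  # tie -> A
        else:
            defining = None

        records.append(
            {
                "gene_id": gene,
                "bin": bin_label,
                "bin_label": render_bin(bin_label, sample_a, sample_b),
                "fpkm_A": a,
                "fpkm_B": b,
                "splice_A": splice_a,
                "splice_B": splice_b,
                "fold": fold,
                "fisher_p": fisher_p,
                "external_call": call,
                "defining_sample": defining,
            }
        )

    table = pd.DataFrame.from_records(records).set_index("gene_id")
    result = BinningResult(
        table=table, sample_a=sample_a, sample_b=sample_b, thresholds=t
    )
    logger.info(
        "binned %d genes (%s vs %s): %s",
        len(table),
        sample_a,
        sample_b,
        result.counts().to_dict(),
    )
    return result
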