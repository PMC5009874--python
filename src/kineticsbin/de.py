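"""Consensus differential-expression calling.

A gene expressed in both samples of a comparison is called over-represented
(OR) only when three conditions agree: fold change at least the threshold,
a significant two-sided Fisher's exact test on estimated fragments per
kilobase normalized against a housekeeping gene (Gapdh by default), and a
concordant call from an external DE method supplied as a file (e.g. GFOLD
output re-expressed as gene/call/score).  Anything short of full agreement
is non-differentially represented (non_DR).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
from scipy.stats import fisher_exact

from .model import (
    GeneExpressionMatrix,
    LibraryStats,
    Thresholds,
    ValidationError,
)

logger = logging.getLogger(__name__)

# external-call vocabulary (closed set)
UP_IN_A = "up_in_A"
UP_IN_B = "up_in_B"
NOT_SIGNIFICANT = "not_significant"
EXTERNAL_CALLS = frozenset({UP_IN_A, UP_IN_B, NOT_SIGNIFICANT})

# consensus status values
OR_A = "OR_A"
OR_B = "OR_B"
NON_DR = "non_DR"

_FLIP = {UP_IN_A: UP_IN_B, UP_IN_B: UP_IN_A, NOT_SIGNIFICANT: NOT_SIGNIFICANT}


@dataclass
class DEResult:
    """Per-gene differential-expression evidence for one sample pair."""

    gene_id: str
    fpkm_A: float
    fpkm_B: float
    fold: float  # ratio >= 1; direction says which sample is higher
    direction: str  # "A" or "B"
    rpk_A: int
    rpk_B: int
    fisher_p: float
    external_call: str | None
    status: str  # OR_A / OR_B / non_DR


def reads_per_kb(fpkm: float, lib: LibraryStats) -> int:
    """Estimated fragments per kilobase of gene length.

    FPKM is fragments per kilobase per million mapped fragments, so
    multiplying by the library's mapped fragments over 1e6 recovers the
    fragment count per kilobase.  Rounded half away from zero.
    """
    if fpkm < 0:
        raise ValidationError("fpkm must be >= 0")
    return int(math.floor(fpkm * lib.mapped_fragments / 1e6 + 0.5))


def fisher_housekeeping_test(
    gene_rpk_A: int, gene_rpk_B: int, hk_rpk_A: int, hk_rpk_B: int
) -> float:
    """Two-sided Fisher's exact p-value of gene vs housekeeping counts.

    The 2x2 table is [[gene_rpk_A, gene_rpk_B], [hk_rpk_A, hk_rpk_B]]; the
    housekeeping row normalizes for library composition.
    """
    cells = (gene_rpk_A, gene_rpk_B, hk_rpk_A, hk_rpk_B)
    if any(c < 0 for c in cells):
        raise ValidationError("all counts must be >= 0")
    if sum(cells) == 0:
        raise ValidationError("all-zero 2x2 table: the exact test is undefined")
    _, p = fisher_exact(
        [[gene_rpk_A, gene_rpk_B], [hk_rpk_A, hk_rpk_B]], alternative="two-sided"
    )
    return float(min(p, 1.0))


def consensus_de(
    fpkm_A: float,
    fpkm_B: float,
    fisher_p: float,
    external_call: str | None,
    t: Thresholds = Thresholds(),
) -> str:
    """Three-conjunct consensus call for a gene expressed in both samples.

    OR_A requires fold(A/B) >= t.fold AND fisher_p < t.fisher_alpha AND an
    external up_in_A call (symmetrically for OR_B); otherwise non_DR.  With
    ``external_call=None`` (single-method mode) the external conjunct is
    dropped.  Callers must pre-filter: both FPKMs must be at or above the
    expression threshold.
    """
    if fpkm_A < t.expression_fpkm or fpkm_B < t.expression_fpkm:
        raise ValidationError(
            "consensus_de requires both samples expressed "
            f"(got {fpkm_A}, {fpkm_B} vs threshold {t.expression_fpkm})"
        )
    if external_call is not None and external_call not in EXTERNAL_CALLS:
        raise ValidationError(f"unknown external call {external_call!r}")
    significant = fisher_p < t.fisher_alpha
    if fpkm_A / fpkm_B >= t.fold and significant:
        if external_call is None or external_call == UP_IN_A:
            return OR_A
    if fpkm_B / fpkm_A >= t.fold and significant:
        if external_call is None or external_call == UP_IN_B:
            return OR_B
    return NON_DR


def read_external_calls(path: str | Path) -> dict[str, str]:
    """Read an external DE-method call file (columns gene_id, call, score)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "call": str})
    for col in ("gene_id", "call"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    bad = ~df["call"].isin(EXTERNAL_CALLS)
    if bad.any():
        raise ValidationError(
            f"{path}: invalid call {df.loc[bad, 'call'].iloc[0]!r} "
            f"(allowed: {sorted(EXTERNAL_CALLS)})"
        )
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(f"{path}: more than one record for gene {dup!r}")
    return dict(zip(df["gene_id"], df["call"]))


def write_external_calls(
    calls: Mapping[str, str], path: str | Path, scores: Mapping[str, float] | None = None
) -> None:
    pd.DataFrame(
        {
            "gene_id": list(calls),
            "call": [calls[g] for g in calls],
            "score": [0.0 if scores is None else scores.get(g, 0.0) for g in calls],
        }
    ).to_csv(path, sep="\t", index=False)


def flip_external_call(call: str | None) -> str | None:
    """Map calls under a swap of the two samples (up_in_A <-> up_in_B)."""
    return None if call is None else _FLIP[call]


def run_de(
    genes: GeneExpressionMatrix,
    sample_a: str,
    sample_b: str,
    libs: Mapping[str, LibraryStats],
    external: Mapping[str, str] | None = None,
    housekeeping: str = "Gapdh",
    thresholds: Thresholds = Thresholds(),
) -> dict[str, DEResult]:
    """Run consensus DE for every gene expressed in both samples.

    Returns a dict keyed by gene id, covering exactly the genes with FPKM at
    or above the expression threshold in both samples.  The housekeeping
    gene must itself be present in the matrix.
    """
    if housekeeping not in genes.fpkm.index:
        raise ValidationError(
            f"housekeeping gene {housekeeping!r} not found in the gene matrix"
        )
    if external is None:
        logger.warning(
            "no external DE calls supplied: consensus degrades to "
            "fold-change + Fisher only (single-method mode)"
        )
    t = thresholds
    hk_a = reads_per_kb(float(genes.fpkm.at[housekeeping, sample_a]), libs[sample_a])
    hk_b = reads_per_kb(float(genes.fpkm.at[housekeeping, sample_b]), libs[sample_b])
    if hk_a == 0 and hk_b == 0:
        raise ValidationError(
            f"housekeeping gene {housekeeping!r} has zero estimated counts in "
            "both samples"
        )

    results: dict[str, DEResult] = {}
    col_a = genes.fpkm[sample_a]
    col_b = genes.fpkm[sample_b]
    both = (col_a >= t.expression_fpkm) & (col_b >= t.expression_fpkm)
    for gene in genes.fpkm.index[both]:
        fa = float(col_a.at[gene])
        fb = float(col_b.at[gene])
        ra = reads_per_kb(fa, libs[sample_a])
        rb = reads_per_kb(fb, libs[sample_b])
        p = fisher_housekeeping_test(ra, rb, hk_a, hk_b)
        call = external.get(gene, NOT_SIGNIFICANT) if external is not None else None
        status = consensus_de(fa, fb, p, call, t)
        direction = "A" if fa >= fb else "B"
        fold = fa / fb if fa >= fb else fb / fa if fa > 0 else math.inf
        results[gene] = DEResult(
            gene_id=gene,
            fpkm_A=fa,
            fpkm_B=fb,
            fold=fold,
            direction=direction,
            rpk_A=ra,
            rpk_B=rb,
            fisher_p=p,
            external_call=call,
            status=status,
        )
    logger.info(
        "DE evaluated for %d genes expressed in both %s and %s",
        len(results),
        sample_a,
        sample_b,
    )
    return results
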