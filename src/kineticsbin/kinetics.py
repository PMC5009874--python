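"""High-resolution transcription kinetics.

Cross-tabulating a gene's bin across two comparisons (for instance time,
E16 vs P0 cytoplasm, crossed with fraction, P0 cytoplasm vs P0 nucleus)
resolves when transcription of the gene was initiated, shut down or
re-initiated.  The cross-tabulation is a complete partition of the shared
gene universe; each (bin1, bin2) cell also maps to a deterministic
human-readable trajectory label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .binning import BIN_LABELS, NO_EX, BinningResult
from .model import GeneExpressionMatrix, ValidationError

__all__ = ["KineticsTable", "cross_tabulate", "interpret_trajectory", "pool_samples"]


@dataclass
class KineticsTable:
    """Cross-tabulation of bin labels from two comparisons.

    ``counts`` has comparison-1 bins as rows and comparison-2 bins as
    columns; ``cells`` maps each (bin1, bin2) pair to its sorted gene list.
    """

    counts: pd.DataFrame
    cells: dict[tuple[str, str], list[str]]

    @property
    def n_genes(self) -> int:
        return int(self.counts.to_numpy().sum())

    def genes_in_cell(self, bin1: str, bin2: str) -> list[str]:
        return self.cells.get((bin1, bin2), [])

    def long_format(self) -> pd.DataFrame:
        """One row per gene: gene_id, bin1, bin2."""
        rows = [
            {"gene_id": g, "bin1": b1, "bin2": b2}
            for (b1, b2), genes in sorted(self.cells.items())
            for g in genes
        ]
        return pd.DataFrame(rows, columns=["gene_id", "bin1", "bin2"])

    def write(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="bin1")


def _as_bin_series(assign) -> pd.Series:
    if isinstance(assign, BinningResult):
        return assign.rendered_bins()
    if isinstance(assign, pd.DataFrame):
        col = "bin_label" if "bin_label" in assign.columns else "bin"
        return assign[col]
    return pd.Series(dict(assign))


def _bin_order(labels: Sequence[str]) -> list[str]:
    """Canonical bins first (in the fixed order), then any extras sorted."""
    present = list(dict.fromkeys(labels))
    ordered = [b for b in BIN_LABELS if b in present]
    extras = sorted(b for b in present if b not in BIN_LABELS)
    # rendered labels (X_Only / OR_X) are extras; keep a stable readable order
    return ordered + extras


def cross_tabulate(assign1, assign2) -> KineticsTable:
    """Cross-tabulate bin assignments from two comparisons.

    Both arguments may be :class:`BinningResult` objects, DataFrames with a
    ``bin``/``bin_label`` column indexed by gene, or gene-to-bin mappings.
    The two gene universes must be identical.
    """
    s1 = _as_bin_series(assign1)
    s2 = _as_bin_series(assign2)
    u1, u2 = set(s1.index), set(s2.index)
    if u1 != u2:
        diff = sorted(u1.symmetric_difference(u2))
        raise ValidationError(
            f"gene universes differ between the two comparisons: {diff}"
        )
    rows = _bin_order(s1.unique())
    cols = _bin_order(s2.unique())
    counts = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    cells: dict[tuple[str, str], list[str]] = {}
    for gene in s1.index:
        key = (s1.at[gene], s2.at[gene])
        cells.setdefault(key, []).append(gene)
    for (b1, b2), genes in cells.items():
        genes.sort()
        counts.at[b1, b2] = len(genes)
    return KineticsTable(counts=counts, cells=cells)


# ---------------------------------------------------------------------------
# Trajectory labels
# ---------------------------------------------------------------------------


def _phase1_phrase(bin1: str, s1: str, s2: str) -> str:
    return {
        "No_Ex": f"not expressed at {s1} or {s2}",
        "A_Only": f"initiated at/before {s1}; shut down before {s2}",
        "B_Only": f"initiated between {s1} and {s2}",
        "OR_A": f"initiated at/before {s1}; downregulated toward {s2}",
        "OR_B": f"initiated at/before {s1}; upregulated toward {s2}",
        "Non_DR": f"steadily expressed at {s1} and {s2}",
    }[bin1]


def _phase2_phrase(bin2: str, s2: str, s3: str) -> str:
    return {
        "No_Ex": f"below threshold at {s2} and {s3}",
        "A_Only": f"expressed at {s2} but off at {s3}",
        "B_Only": f"re-initiated at {s3}",
        "OR_A": f"downregulated at {s3}",
        "OR_B": f"continued upregulation at {s3}",
        "Non_DR": f"maintained through {s3}",
    }[bin2]


def interpret_trajectory(
    bin1: str, bin2: str, stage_names: Sequence[str] = ("E16", "P0", "P0 (nuclear)")
) -> str:
    """Deterministic trajectory label for a (bin1, bin2) cell.

    ``stage_names`` are the three assayed states: comparison 1 contrasts
    the first two, comparison 2 the last two.  Bins are given canonically
    (A_Only means the first sample of its comparison).  The mapping is
    total over the 6x6 bin pairs and every pair has a distinct label.
    """
    for b, arg in ((bin1, "bin1"), (bin2, "bin2")):
        if b not in BIN_LABELS:
            raise ValidationError(f"{arg} must be one of {BIN_LABELS}, got {b!r}")
    s1, s2, s3 = stage_names
    if bin1 == NO_EX and bin2 == NO_EX:
        return "not expressed at any assayed stage/fraction"
    return f"{_phase1_phrase(bin1, s1, s2)}; {_phase2_phrase(bin2, s2, s3)}"


def trajectory_table(
    stage_names: Sequence[str] = ("E16", "P0", "P0 (nuclear)")
) -> pd.DataFrame:
    """The full 6x6 lookup of trajectory labels."""
    return pd.DataFrame(
        {
            b2: {b1: interpret_trajectory(b1, b2, stage_names) for b1 in BIN_LABELS}
            for b2 in BIN_LABELS
        }
    )


def pool_samples(
    genes: GeneExpressionMatrix,
    samples: Sequence[str],
    name: str,
    how: str = "max",
) -> GeneExpressionMatrix:
    """Pool several samples (e.g. the two P0 fractions) into one column.

    ``how='max'`` (default) takes the per-gene maximum FPKM, so a gene
    expressed in either fraction counts as expressed in the pool;
    ``how='sum'`` adds the fractions instead.
    """
    missing = [s for s in samples if s not in genes.fpkm.columns]
    if missing:
        raise ValidationError(f"samples not in matrix: {missing}")
    if how == "max":
        pooled = genes.fpkm[list(samples)].max(axis=1)
    elif how == "sum":
        pooled = genes.fpkm[list(samples)].sum(axis=1)
    else:
        raise ValidationError("how must be 'max' or 'sum'")
    out = genes.fpkm.copy()
    out[name] = pooled
    return GeneExpressionMatrix(fpkm=out)
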