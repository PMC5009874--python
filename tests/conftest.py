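import numpy as np
import pandas as pd
import pytest

from kineticsbin import (
    ExpressionMatrix,
    SimulationConfig,
    Thresholds,
    TranscriptModel,
    simulate_comparison,
)


@pytest.fixture(scope="session")
def thresholds():
    return Thresholds()


@pytest.fixture(scope="session")
def small_sim():
    """A small planted comparison shared by several test modules."""
    cfg = SimulationConfig(
        seed=11,
        n_genes_per_bin={
            "No_Ex": 20,
            "A_Only": 15,
            "B_Only": 15,
            "OR_A": 10,
            "OR_B": 10,
            "Non_DR": 20,
        },
    )
    return cfg, simulate_comparison(cfg)


@pytest.fixture()
def random_matrix():
    """Random isoform matrix: 50 isoforms over 17 genes, 3 samples."""
    rng = np.random.default_rng(42)
    iso_ids = [f"tx{i:03d}" for i in range(50)]
    genes = pd.Series(
        [f"g{i % 17:02d}" for i in range(50)], index=iso_ids, name="gene_id"
    )
    fpkm = pd.DataFrame(
        rng.gamma(1.0, 5.0, size=(50, 3)),
        index=iso_ids,
        columns=["s1", "s2", "s3"],
    )
    return ExpressionMatrix(fpkm=fpkm, gene_of_isoform=genes)


def random_transcripts(rng, n_genes=10, max_iso=3):
    """Toy multi-exon transcript models for junction tests."""
    out = []
    for gi in range(n_genes):
        gene = f"gene{gi:02d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_iso = int(rng.integers(1, max_iso + 1))
        # a shared exon skeleton for the gene, isoforms use subsets
        n_ex = int(rng.integers(2, 7))
        skeleton = []
        pos = gi * 100_000
        for _ in range(n_ex):
            pos += int(rng.integers(50, 500))  # intergenic/intron gap
            length = int(rng.integers(5, 300))
            skeleton.append((pos, pos + length))
            pos += length
        for ti in range(n_iso):
            keep = sorted(
                rng.choice(n_ex, size=int(rng.integers(2, n_ex + 1)), replace=False)
            )
            out.append(
                TranscriptModel(
                    transcript_id=f"{gene}.t{ti}",
                    gene_id=gene,
                    chrom="chr1",
                    strand=strand,
                    exons=[skeleton[i] for i in keep],
                )
            )
    return out
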