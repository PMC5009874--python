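"""Exon-exon junction enumeration and probe selection."""

import numpy as np
import pytest

from kineticsbin import (
    Thresholds,
    TranscriptModel,
    enumerate_junctions,
    select_probes,
)
from kineticsbin.junctions import (
    NOT_UNIQUE,
    SHORT_FLANK,
    SINGLE_ISOFORM_GENE,
)
from conftest import random_transcripts


def brute_force_junctions(transcripts, expressed):
    """Oracle: per-transcript adjacent-exon pairs, grouped by key."""
    grouped = {}
    for tx in transcripts:
        if expressed is not None and tx.transcript_id not in expressed:
            continue
        for (s1, e1), (s2, e2) in zip(tx.exons, tx.exons[1:]):
            key = (tx.gene_id, e1, s2)
            grouped.setdefault(key, []).append((tx.transcript_id, e1 - s1, e2 - s2))
    return grouped


def _tx(tid, gene, exons, strand="+"):
    return TranscriptModel(tid, gene, "chr1", strand, exons=exons)


class TestEnumerate:
    def test_single_exon_contributes_nothing(self):
        assert enumerate_junctions([_tx("t1", "g", [(0, 100)])]) == []

    def test_shared_and_distinct_junctions(self):
        """Two isoforms sharing the exon1-exon2 junction but differing at
        exon2-exon3 give one shared and two singleton junctions."""
        t1 = _tx("t1", "g", [(0, 100), (200, 300), (400, 500)])
        t2 = _tx("t2", "g", [(0, 100), (200, 300), (600, 700)])
        junctions = {(j.donor_end, j.acceptor_start): j for j in enumerate_junctions([t1, t2])}
        assert len(junctions) == 3
        assert junctions[(100, 200)].transcripts == {"t1", "t2"}
        assert junctions[(300, 400)].transcripts == {"t1"}
        assert junctions[(300, 600)].transcripts == {"t2"}

    def test_flanks_are_min_over_carriers(self):
        t1 = _tx("t1", "g", [(0, 100), (200, 300)])  # left flank 100
        t2 = _tx("t2", "g", [(60, 100), (200, 450)])  # left flank 40
        (j,) = enumerate_junctions([t1, t2])
        assert j.left_flank == 40
        assert j.right_flank == 100

    def test_expressed_filter(self):
        t1 = _tx("t1", "g", [(0, 100), (200, 300)])
        t2 = _tx("t2", "g", [(0, 100), (400, 500)])
        junctions = enumerate_junctions([t1, t2], expressed_transcripts={"t1"})
        assert len(junctions) == 1
        assert junctions[0].acceptor_start == 200

    def test_matches_brute_force_grouping(self):
        rng = np.random.default_rng(19)
        txs = random_transcripts(rng, n_genes=12, max_iso=4)
        expressed = {t.transcript_id for t in txs if rng.random() < 0.7}
        junctions = enumerate_junctions(txs, expressed)
        oracle = brute_force_junctions(txs, expressed)
        assert len(junctions) == len(oracle)
        for j in junctions:
            carriers = oracle[(j.gene_id, j.donor_end, j.acceptor_start)]
            assert j.transcripts == {c[0] for c in carriers}
            assert j.left_flank == min(c[1] for c in carriers)
            assert j.right_flank == min(c[2] for c in carriers)


class TestSelectProbes:
    def _records(self, exons_a, exons_b, min_flank=13):
        t1 = _tx("t1", "g", exons_a)
        t2 = _tx("t2", "g", exons_b)
        junctions = enumerate_junctions([t1, t2])
        return select_probes(
            junctions, {"g": 2}, Thresholds(min_flank=min_flank)
        )

    def test_flank_12_eliminated_13_kept(self):
        """The boundary of the flank rule: 12 bases out, 13 bases in."""
        kept = self._records(
            [(0, 13), (200, 300)], [(0, 13), (400, 500)]
        )
        assert all(r.kept for r in kept)
        dropped = self._records(
            [(0, 12), (200, 300)], [(0, 12), (400, 500)]
        )
        assert all(not r.kept and r.rejection_reason == SHORT_FLANK for r in dropped)

    def test_shared_junction_not_unique(self):
        records = self._records(
            [(0, 100), (200, 300), (400, 500)],
            [(0, 100), (200, 300), (600, 700)],
        )
        by_key = {
            (r.junction.donor_end, r.junction.acceptor_start): r for r in records
        }
        assert by_key[(100, 200)].rejection_reason == NOT_UNIQUE
        assert by_key[(300, 400)].kept
        assert by_key[(300, 600)].kept

    def test_single_isoform_gene_rejected(self):
        t1 = _tx("t1", "g", [(0, 100), (200, 300)])
        junctions = enumerate_junctions([t1])
        records = select_probes(junctions, {"g": 1})
        assert records[0].rejection_reason == SINGLE_ISOFORM_GENE
        assert not records[0].kept

    def test_matches_brute_force_filter(self):
        """Randomized annotations: kept set equals a literal reapplication
        of the three rules."""
        rng = np.random.default_rng(21)
        for _ in range(10):
            txs = random_transcripts(rng, n_genes=8, max_iso=4)
            expressed = {t.transcript_id for t in txs if rng.random() < 0.8}
            counts = {}
            for t in txs:
                if t.transcript_id in expressed:
                    counts[t.gene_id] = counts.get(t.gene_id, 0) + 1
            junctions = enumerate_junctions(txs, expressed)
            records = select_probes(junctions, counts)
            for r in records:
                j = r.junction
                expected = (
                    counts.get(j.gene_id, 0) >= 2
                    and len(j.transcripts) == 1
                    and min(j.left_flank, j.right_flank) >= 13
                )
                assert r.kept == expected

    def test_min_flank_monotone(self):
        rng = np.random.default_rng(27)
        txs = random_transcripts(rng, n_genes=10, max_iso=3)
        counts = {}
        for t in txs:
            counts[t.gene_id] = counts.get(t.gene_id, 0) + 1
        junctions = enumerate_junctions(txs)
        kept_sets = []
        for mf in (5, 13, 40):
            records = select_probes(junctions, counts, Thresholds(min_flank=mf))
            kept_sets.append(
                {
                    (r.junction.gene_id, r.junction.donor_end, r.junction.acceptor_start)
                    for r in records
                    if r.kept
                }
            )
        assert kept_sets[0] >= kept_sets[1] >= kept_sets[2]

    def test_no_kept_probe_without_two_expressed_tx(self):
        rng = np.random.default_rng(33)
        txs = random_transcripts(rng, n_genes=10, max_iso=3)
        counts = {}
        for t in txs:
            counts[t.gene_id] = counts.get(t.gene_id, 0) + 1
        records = select_probes(enumerate_junctions(txs), counts)
        for r in records:
            if counts.get(r.junction.gene_id, 0) < 2:
                assert not r.kept
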