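"""Unique exon-exon junction probe selection.

A microarray probe spanning a splice junction is diagnostic for a single
isoform only when that junction occurs in exactly one expressed transcript
of its gene.  Junctions are enumerated per gene over expressed transcripts;
a probe is kept when the gene has at least two expressed transcripts, the
junction is unique among them, and the exon length on each side of the
junction (the flank available to the probe) is at least 13 bases —
junctions with flanks of 12 bases or fewer are eliminated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .model import Thresholds, TranscriptModel, ValidationError

__all__ = ["Junction", "ProbeRecord", "enumerate_junctions", "select_probes", "write_probes_bed"]

# rejection reasons
NOT_UNIQUE = "not_unique"
SHORT_FLANK = "short_flank"
SINGLE_ISOFORM_GENE = "single_isoform_gene"


@dataclass
class Junction:
    """A distinct exon-exon junction of one gene.

    Coordinates are genome-forward and 0-based: ``donor_end`` is the
    exclusive end of the upstream exon, ``acceptor_start`` the start of the
    downstream exon.  Flanks are the adjacent exon lengths; when several
    transcripts share the junction the minimum over carriers is used (a
    probe must fit all of them).
    """

    gene_id: str
    chrom: str
    strand: str
    donor_end: int
    acceptor_start: int
    left_flank: int
    right_flank: int
    transcripts: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.donor_end >= self.acceptor_start:
            raise ValidationError(
                f"junction {self.gene_id} {self.donor_end}..{self.acceptor_start}: "
                "donor_end must precede acceptor_start"
            )
        if self.left_flank < 1 or self.right_flank < 1:
            raise ValidationError("junction flanks must be >= 1 base")


@dataclass
class ProbeRecord:
    junction: Junction
    unique: bool
    kept: bool
    rejection_reason: str | None = None


def enumerate_junctions(
    transcripts: Sequence[TranscriptModel],
    expressed_transcripts: Iterable[str] | None = None,
) -> list[Junction]:
    """Enumerate distinct exon-exon junctions per gene.

    Only transcripts in ``expressed_transcripts`` contribute (all of them
    when None).  A junction is keyed by (gene, donor_end, acceptor_start);
    its ``transcripts`` field lists every contributing isoform that carries
    it and its flanks are the minimum adjacent exon lengths over those
    isoforms.  Single-exon transcripts contribute nothing.
    """
    expressed = None if expressed_transcripts is None else set(expressed_transcripts)
    agg: dict[tuple[str, int, int], dict] = {}
    for tx in transcripts:
        if expressed is not None and tx.transcript_id not in expressed:
            continue
        for (s1, e1), (s2, e2) in zip(tx.exons, tx.exons[1:]):
            key = (tx.gene_id, e1, s2)
            entry = agg.setdefault(
                key,
                {
                    "chrom": tx.chrom,
                    "strand": tx.strand,
                    "left": e1 - s1,
                    "right": e2 - s2,
                    "txs": set(),
                },
            )
            entry["left"] = min(entry["left"], e1 - s1)
            entry["right"] = min(entry["right"], e2 - s2)
            entry["txs"].add(tx.transcript_id)
    return [
        Junction(
            gene_id=gene,
            chrom=entry["chrom"],
            strand=entry["strand"],
            donor_end=donor,
            acceptor_start=acceptor,
            left_flank=entry["left"],
            right_flank=entry["right"],
            transcripts=frozenset(entry["txs"]),
        )
        for (gene, donor, acceptor), entry in sorted(agg.items())
    ]


def select_probes(
    junctions: Sequence[Junction],
    gene_expressed_tx_counts: Mapping[str, int],
    t: Thresholds = Thresholds(),
) -> list[ProbeRecord]:
    """Apply the three probe-selection rules to enumerated junctions.

    A junction is kept iff its gene has at least two expressed transcripts,
    it occurs in exactly one of them, and both flanks are at least
    ``t.min_flank`` bases.  Rejected records carry the first failing rule as
    their reason (gene multi-isoform status, then uniqueness, then flanks).
    """
    records = []
    for j in junctions:
        unique = len(j.transcripts) == 1
        if gene_expressed_tx_counts.get(j.gene_id, 0) < 2:
            reason = SINGLE_ISOFORM_GENE
        elif not unique:
            reason = NOT_UNIQUE
        elif min(j.left_flank, j.right_flank) < t.min_flank:
            reason = SHORT_FLANK
        else:
            reason = None
        records.append(
            ProbeRecord(junction=j, unique=unique, kept=reason is None, rejection_reason=reason)
        )
    return records


def write_probes_bed(records: Sequence[ProbeRecord], path: str | Path, kept_only: bool = True) -> None:
    """Write probe junctions as BED intervals spanning donor..acceptor.

    The BED name field is gene|transcripts; score 1 for kept probes, 0
    otherwise.
    """
    with open(path, "w") as fh:
        for r in records:
            if kept_only and not r.kept:
                continue
            j = r.junction
            name = f"{j.gene_id}|{','.join(sorted(j.transcripts))}"
            fh.write(
                f"{j.chrom}\t{j.donor_end}\t{j.acceptor_start}\t{name}\t"
                f"{int(r.kept)}\t{j.strand}\n"
            )
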