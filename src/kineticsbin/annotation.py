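"""Term enrichment and network-based gene-list expansion.

Two black-box web services of the original workflow are replaced by
in-package equivalents operating on user-supplied files: term enrichment is
a one-sided hypergeometric test with Benjamini-Hochberg control over a GMT
annotation, and partner discovery is an iterative neighborhood expansion
over a weighted gene-gene interaction network in which candidate partners
are ranked by summed edge weight to the current list and only genes
expressed in the RNA-Seq data may join.  The expansion is repeated until no
gene is added (convergence).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .model import Thresholds, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationSet",
    "ExpansionTrace",
    "read_gmt",
    "write_gmt",
    "read_network",
    "write_network",
    "enrich",
    "expand_gene_list",
]


@dataclass
class AnnotationSet:
    """Flat term-to-genes annotation with an explicit background universe."""

    terms: dict[str, tuple[str, frozenset[str]]]  # term_id -> (name, genes)
    background: frozenset[str]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValidationError("annotation set has no terms")
        for term_id, (_, genes) in self.terms.items():
            if not genes:
                raise ValidationError(f"term {term_id!r} has an empty gene set")
            stray = genes - self.background
            if stray:
                raise ValidationError(
                    f"term {term_id!r} annotates genes outside the background: "
                    f"{sorted(stray)[:5]}"
                )


def read_gmt(path: str | Path, background: Iterable[str] | None = None) -> AnnotationSet:
    """Read a GMT file (term_id <tab> description <tab> gene ...).

    If no background is given, the union of all term genes is used.
    """
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs term, description and "
                    "at least one gene"
                )
            term_id, name, genes = parts[0], parts[1], parts[2:]
            if term_id in terms:
                raise ValidationError(f"{path}:{lineno}: duplicate term {term_id!r}")
            terms[term_id] = (name, frozenset(g for g in genes if g))
    if background is None:
        bg = frozenset().union(*(g for _, g in terms.values()))
    else:
        bg = frozenset(background)
    return AnnotationSet(terms=terms, background=bg)


def write_gmt(ann: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term_id, (name, genes) in ann.terms.items():
            fh.write("\t".join([term_id, name, *sorted(genes)]) + "\n")


def read_network(path: str | Path) -> nx.Graph:
    """Read a weighted edge list (gene_a <tab> gene_b <tab> weight)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    for col in ("gene_a", "gene_b", "weight"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    g = nx.Graph()
    seen: set[frozenset[str]] = set()
    for _, row in df.iterrows():
        a, b, w = row["gene_a"], row["gene_b"], float(row["weight"])
        if a == b:
            raise ValidationError(f"{path}: self-loop on {a!r}")
        if w <= 0:
            raise ValidationError(f"{path}: non-positive weight on {a!r}-{b!r}")
        key = frozenset((a, b))
        if key in seen:
            raise ValidationError(f"{path}: duplicate edge {a!r}-{b!r}")
        seen.add(key)
        g.add_edge(a, b, weight=w)
    return g


def write_network(g: nx.Graph, path: str | Path) -> None:
    rows = [
        {"gene_a": a, "gene_b": b, "weight": d.get("weight", 1.0)}
        for a, b, d in sorted(g.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------


def enrich(
    query: Iterable[str],
    annotations: AnnotationSet,
    t: Thresholds = Thresholds(),
    ease: bool = False,
) -> pd.DataFrame:
    """Hypergeometric term enrichment with Benjamini-Hochberg control.

    For each term the one-sided p-value is the probability of an overlap at
    least as large as observed when drawing ``list_size`` genes from the
    background.  With ``ease=True`` the observed overlap is discounted by
    one before the tail is taken (the more conservative EASE variant).
    Returns one row per term sorted by (q, p), with ``significant`` set
    where q <= t.benjamini_alpha.
    """
    query_set = frozenset(query)
    if not query_set:
        raise ValidationError("empty query gene list")
    stray = query_set - annotations.background
    if stray:
        raise ValidationError(
            f"query genes outside the background: {sorted(stray)[:5]}"
        )
    M = len(annotations.background)
    n = len(query_set)
    rows = []
    for term_id, (name, genes) in annotations.terms.items():
        k = len(query_set & genes)
        K = len(genes)
        observed = max(k - 1, 0) if ease else k
        # P(X >= observed) for X ~ Hypergeom(M, K, n); sf(x) = P(X > x)
        p = float(hypergeom.sf(observed - 1, M, K, n)) if observed > 0 else 1.0
        rows.append(
            {
                "term_id": term_id,
                "term_name": name,
                "overlap": k,
                "list_size": n,
                "term_size": K,
                "background_size": M,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    _, q, _, _ = multipletests(out["p"], method="fdr_bh")
    out["benjamini_q"] = q
    out["significant"] = out["benjamini_q"] <= t.benjamini_alpha
    out = out.sort_values(["benjamini_q", "p", "term_id"]).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Network expansion
# ---------------------------------------------------------------------------


@dataclass
class ExpansionRound:
    """One round of the expansion: what was scored and what joined."""

    input_list: list[str]
    candidates: list[str]  # top-ranked non-members, before the expressed filter
    added: list[str]  # candidates that survived the expressed filter


@dataclass
class ExpansionTrace:
    """Full record of an iterative neighborhood expansion."""

    seed: list[str]
    rounds: list[ExpansionRound] = field(default_factory=list)
    final_list: list[str] = field(default_factory=list)
    converged: bool = False

    @property
    def iterations(self) -> int:
        """Number of rounds executed (including the one detecting convergence)."""
        return len(self.rounds)

    @property
    def growth_iterations(self) -> int:
        """Number of rounds that added at least one gene."""
        return sum(1 for r in self.rounds if r.added)


def expand_gene_list(
    seed: Iterable[str],
    net: nx.Graph,
    expressed: Iterable[str],
    partners_per_round: int = 20,
    max_iter: int = 10,
) -> ExpansionTrace:
    """Iteratively expand a gene list over an interaction network.

    Each round scores every non-member gene by its summed edge weight to
    the current list, takes the top ``partners_per_round`` candidates (ties
    broken lexicographically by gene id), keeps only those expressed in the
    RNA-Seq data, and adds the survivors.  The process stops when a round
    adds nothing (convergence) or after ``max_iter`` rounds.
    """
    seed_list = sorted(set(seed))
    if not seed_list:
        raise ValidationError("seed gene list is empty")
    if partners_per_round < 1:
        raise ValidationError("partners_per_round must be >= 1")
    expressed_set = set(expressed)
    missing = [g for g in seed_list if g not in net]
    if missing:
        logger.warning(
            "%d seed gene(s) absent from the network (kept in the list, "
            "contribute no edges): %s",
            len(missing),
            missing[:5],
        )

    trace = ExpansionTrace(seed=seed_list)
    current = set(seed_list)
    for _ in range(max_iter):
        scores: dict[str, float] = {}
        for member in current:
            if member not in net:
                continue
            for nbr, data in net[member].items():
                if nbr in current:
                    continue
                scores[nbr] = scores.get(nbr, 0.0) + float(data.get("weight", 1.0))
        ranked = sorted(scores, key=lambda g: (-scores[g], g))
        candidates = ranked[:partners_per_round]
        added = sorted(g for g in candidates if g in expressed_set)
        trace.rounds.append(
            ExpansionRound(
                input_list=sorted(current), candidates=candidates, added=added
            )
        )
        if not added:
            trace.converged = True
            break
        current.update(added)
    trace.final_list = sorted(current)
    return trace
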