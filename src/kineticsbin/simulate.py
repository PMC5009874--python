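"""Synthetic inputs with planted ground truth.

The generator emits the statistical structure the binning pipeline assumes:
a two-sample isoform FPKM matrix in which every gene is planted into a
known expression bin and alternative-splicing category with a safety margin
around the 1-FPKM threshold, fragment counts consistent with the library
sizes, external DE calls consistent with the planted truth, a weighted
interaction network with a planted shelled module, and a GMT annotation
with one planted enriched term.  Every draw flows through one seeded
generator, so identical configuration and seed give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import binning as _bi
from . import de as _de
from .annotation import AnnotationSet
from .model import ExpressionMatrix, LibraryStats, Thresholds, ValidationError

import networkx as nx

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_comparison",
    "simulate_network_and_annotations",
    "worked_example_fpkm",
    "worked_example_matrix",
]

_MULTI_CATS = (_bi.MI, _bi.MOAT, _bi.MIBT)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic-data generator.

    Defaults describe a realistic two-sample bulk comparison: roughly a
    thousand genes spread over all six bins, mammalian-like isoform counts
    (most genes with 1-2 annotated isoforms), high-depth libraries of about
    sixty million mapped fragments, and over-representation folds between
    2.5x and 20x so planted OR genes clear the 2-fold threshold with margin.
    """

    seed: int = 0
    sample_names: tuple[str, str] = ("A", "B")
    n_genes_per_bin: dict = field(
        default_factory=lambda: {
            _bi.NO_EX: 250,
            _bi.A_ONLY: 150,
            _bi.B_ONLY: 150,
            _bi.OR_A: 120,
            _bi.OR_B: 120,
            _bi.NON_DR: 250,
        }
    )
    isoform_count_distribution: dict = field(
        default_factory=lambda: {1: 0.4, 2: 0.3, 3: 0.2, 4: 0.1}
    )
    splice_category_mix: dict = field(
        default_factory=lambda: {_bi.SI: 0.4, _bi.MI: 0.3, _bi.MOAT: 0.2, _bi.MIBT: 0.1}
    )
    library_sizes: dict | None = None  # sample -> mapped fragments
    fold_range_OR: tuple[float, float] = (2.5, 20.0)
    housekeeping: str = "Gapdh"
    housekeeping_fpkm: float = 100.0
    thresholds: Thresholds = field(default_factory=Thresholds)
    # network / annotation structure
    network_module_sizes: tuple[int, ...] = (8, 6, 5, 4)  # seed + 3 growth shells
    n_noise_edges: int = 300
    n_background_genes: int = 2000
    n_terms: int = 50
    term_size_range: tuple[int, int] = (30, 60)
    planted_term_size: int = 40
    query_size: int = 25
    planted_term_fraction: float = 0.8

    def __post_init__(self) -> None:
        for name in ("isoform_count_distribution", "splice_category_mix"):
            probs = getattr(self, name)
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValidationError(f"{name} probabilities must sum to 1")
        if self.fold_range_OR[0] < self.thresholds.fold:
            raise ValidationError(
                "fold_range_OR lower bound must be >= the fold threshold"
            )
        if self.library_sizes is None:
            a, b = self.sample_names
            self.library_sizes = {a: 60_000_000, b: 62_000_000}


@dataclass
class GroundTruth:
    """Planted truth accompanying a simulation."""

    bins: dict[str, str] | None = None  # gene -> canonical bin
    splice: dict[tuple[str, str], str | None] | None = None  # (gene, sample) -> cat
    de_direction: dict[str, str] | None = None  # gene -> external-call value
    module_shells: list[list[str]] | None = None
    unexpressed_decoy: str | None = None
    planted_term_id: str | None = None
    query: list[str] | None = None


# ---------------------------------------------------------------------------
# FPKM structure helpers
# ---------------------------------------------------------------------------


def _sum_interval(cat: str, k: int, t: float) -> tuple[float, float]:
    """Feasible gene-FPKM sums for a splice category with k isoforms.

    Bounds keep every generated value at least 5% away from the threshold
    (in practice 10%), so float edges never flip a planted call.
    """
    if cat == _bi.SI:
        return (1.10 * t, 60.0 * t)
    if cat == _bi.MI:
        return (2.20 * t, 60.0 * t)
    if cat == _bi.MOAT:
        return (1.30 * t, 60.0 * t)
    if cat == _bi.MIBT:
        return (1.10 * t, 0.72 * k * t)
    raise ValidationError(f"unknown splice category {cat!r}")


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _decompose(
    rng: np.random.Generator, total: float, cat: str | None, k: int, t: float
) -> np.ndarray:
    """Split a gene FPKM sum into k isoform values matching the category."""
    if k == 1:
        return np.array([total])
    if cat is None:  # non-expressed sample: any split of a small total
        return rng.dirichlet(np.ones(k)) * total
    if cat == _bi.MIBT:
        for _ in range(500):
            parts = rng.dirichlet(np.full(k, 5.0)) * total
            if parts.max() <= 0.90 * t and parts.min() >= 0.01 * t:
                return parts
        raise ValidationError("could not decompose a MIBT gene; total too high")
    if cat == _bi.MOAT:
        r_lo = 0.02 * t * (k - 1)
        r_hi = min(0.85 * t * (k - 1), total - 1.06 * t)
        rest = rng.uniform(r_lo, max(r_lo, r_hi))
        for _ in range(500):
            small = rng.dirichlet(np.full(k - 1, 5.0)) * rest
            if small.max() <= 0.90 * t:
                return np.concatenate(([total - rest], small))
        raise ValidationError("could not decompose a MOAT gene")
    if cat == _bi.MI:
        e = k - 2
        extras = np.array([])
        if e > 0:
            hi_e = min(0.30 * t, (total - 2.14 * t) / e)
            extras = rng.uniform(0.01 * t, max(0.011 * t, hi_e), size=e)
        rem = total - extras.sum()
        u = rng.uniform(1.06 * t / rem, 1 - 1.06 * t / rem)
        return np.concatenate(([u * rem, rem - u * rem], extras))
    raise ValidationError(f"unknown splice category {cat!r}")


def _draw_category(rng: np.random.Generator, mix: Mapping[str, float], multi_only: bool) -> str:
    cats = list(mix)
    probs = np.array([mix[c] for c in cats], dtype=float)
    if multi_only:
        keep = [i for i, c in enumerate(cats) if c in _MULTI_CATS]
        if not keep or probs[keep].sum() == 0:
            raise ValidationError(
                "splice_category_mix has no mass on multi-isoform categories"
            )
        cats = [cats[i] for i in keep]
        probs = probs[keep]
    probs = probs / probs.sum()
    return str(rng.choice(cats, p=probs))


def _draw_k(rng: np.random.Generator, dist: Mapping[int, float], cat: str) -> int:
    if cat == _bi.SI:
        return 1
    ks = [k for k in sorted(dist) if k >= 2]
    probs = np.array([dist[k] for k in ks], dtype=float)
    if probs.sum() == 0:
        raise ValidationError(
            "isoform_count_distribution has no mass on counts >= 2"
        )
    return int(rng.choice(ks, p=probs / probs.sum()))


# ---------------------------------------------------------------------------
# Comparison simulation
# ---------------------------------------------------------------------------


def simulate_comparison(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, dict[str, LibraryStats], dict[str, str], GroundTruth]:
    """Generate a two-sample isoform FPKM matrix with planted bins.

    Every gene satisfies its planted bin's defining inequalities with
    margin; planted OR genes are verified significant under the exact test
    at generation time (infeasible configurations raise).  Returns the
    isoform matrix, library stats, external DE calls and the ground truth.
    """
    rng = np.random.default_rng(cfg.seed)
    t = cfg.thresholds.expression_fpkm
    sa, sb = cfg.sample_names
    libs = {s: LibraryStats(s, int(n)) for s, n in cfg.library_sizes.items()}
    f_lo_cfg, f_hi_cfg = cfg.fold_range_OR

    hk_rpk_a = _de.reads_per_kb(cfg.housekeeping_fpkm, libs[sa])
    hk_rpk_b = _de.reads_per_kb(cfg.housekeeping_fpkm, libs[sb])

    plan = [b for b, n in cfg.n_genes_per_bin.items() for _ in range(n)]
    for b in set(plan):
        if b not in _bi.BIN_LABELS:
            raise ValidationError(f"unknown bin {b!r} in n_genes_per_bin")
    rng.shuffle(plan)

    bins: dict[str, str] = {}
    splice: dict[tuple[str, str], str | None] = {}
    calls: dict[str, str] = {}
    rows = []  # (isoform_id, gene_id, fpkm_a, fpkm_b)

    def emit(gene: str, k: int, s_a: float, s_b: float, cat_a, cat_b) -> None:
        parts_a = _decompose(rng, s_a, cat_a, k, t)
        parts_b = _decompose(rng, s_b, cat_b, k, t)
        for i in range(k):
            rows.append((f"{gene}.{i + 1}", gene, float(parts_a[i]), float(parts_b[i])))
        splice[(gene, sa)] = cat_a
        splice[(gene, sb)] = cat_b

    for idx, planted in enumerate(plan, start=1):
        gene = f"G{idx:05d}"
        bins[gene] = planted

        if planted == _bi.NO_EX:
            k = _draw_k(rng, cfg.isoform_count_distribution, _draw_category(rng, cfg.splice_category_mix, False))
            emit(gene, k, rng.uniform(0, 0.5 * t), rng.uniform(0, 0.5 * t), None, None)
            calls[gene] = _de.NOT_SIGNIFICANT
            continue

        if planted in (_bi.A_ONLY, _bi.B_ONLY):
            cat = _draw_category(rng, cfg.splice_category_mix, False)
            k = _draw_k(rng, cfg.isoform_count_distribution, cat)
            lo, hi = _sum_interval(cat, k, t)
            s_on = _log_uniform(rng, lo, min(hi, 50.0 * t))
            s_off = rng.uniform(0, 0.5 * t)
            if planted == _bi.A_ONLY:
                emit(gene, k, s_on, s_off, cat, None)
            else:
                emit(gene, k, s_off, s_on, None, cat)
            calls[gene] = _de.NOT_SIGNIFICANT
            continue

        if planted == _bi.NON_DR:
            ok = False
            for _ in range(200):
                cat_a = _draw_category(rng, cfg.splice_category_mix, False)
                cat_b = (
                    _bi.SI
                    if cat_a == _bi.SI
                    else _draw_category(rng, cfg.splice_category_mix, True)
                )
                k = _draw_k(rng, cfg.isoform_count_distribution, cat_a)
                lo_a, hi_a = _sum_interval(cat_a, k, t)
                lo_b, hi_b = _sum_interval(cat_b, k, t)
                s_a = _log_uniform(rng, lo_a, min(hi_a, 30.0 * t))
                blo, bhi = max(lo_b, s_a / 1.6), min(hi_b, s_a * 1.6)
                if blo >= bhi:
                    continue
                s_b = rng.uniform(blo, bhi)
                emit(gene, k, s_a, s_b, cat_a, cat_b)
                calls[gene] = _de.NOT_SIGNIFICANT
                ok = True
                break
            if not ok:
                raise ValidationError(
                    f"could not generate a Non_DR gene under this configuration"
                )
            continue

        # OR bins: the over-represented sample is 'hi'
        a_is_hi = planted == _bi.OR_A
        ok = False
        for _ in range(200):
            cat_hi = _draw_category(rng, cfg.splice_category_mix, False)
            cat_lo = (
                _bi.SI
                if cat_hi == _bi.SI
                else _draw_category(rng, cfg.splice_category_mix, True)
            )
            k = _draw_k(rng, cfg.isoform_count_distribution, cat_hi)
            lo_h, hi_h = _sum_interval(cat_hi, k, t)
            lo_l, hi_l = _sum_interval(cat_lo, k, t)
            hi_l = min(hi_l, 25.0 * t)
            f_min = max(f_lo_cfg, lo_h / hi_l)
            f_max = min(f_hi_cfg, hi_h / lo_l)
            if f_min >= f_max:
                continue
            f = rng.uniform(f_min, f_max)
            s_lo = rng.uniform(max(lo_l, lo_h / f), min(hi_l, hi_h / f))
            s_hi = f * s_lo
            lib_hi, lib_lo = (libs[sa], libs[sb]) if a_is_hi else (libs[sb], libs[sa])
            rpk_hi = _de.reads_per_kb(s_hi, lib_hi)
            rpk_lo = _de.reads_per_kb(s_lo, lib_lo)
            hk_hi, hk_lo = (hk_rpk_a, hk_rpk_b) if a_is_hi else (hk_rpk_b, hk_rpk_a)
            p = _de.fisher_housekeeping_test(rpk_hi, rpk_lo, hk_hi, hk_lo)
            if p >= cfg.thresholds.fisher_alpha:
                continue
            if a_is_hi:
                emit(gene, k, s_hi, s_lo, cat_hi, cat_lo)
                calls[gene] = _de.UP_IN_A
            else:
                emit(gene, k, s_lo, s_hi, cat_lo, cat_hi)
                calls[gene] = _de.UP_IN_B
            ok = True
            break
        if not ok:
            raise ValidationError(
                "planted OR gene cannot reach exact-test significance at the "
                "configured library sizes and fold range"
            )

    # housekeeping gene, stably expressed in both samples
    hk = cfg.housekeeping
    rows.append((f"{hk}.1", hk, cfg.housekeeping_fpkm, cfg.housekeeping_fpkm))
    bins[hk] = _bi.NON_DR
    splice[(hk, sa)] = _bi.SI
    splice[(hk, sb)] = _bi.SI
    calls[hk] = _de.NOT_SIGNIFICANT

    df = pd.DataFrame(rows, columns=["isoform_id", "gene_id", sa, sb])
    matrix = ExpressionMatrix(
        fpkm=df.set_index("isoform_id")[[sa, sb]],
        gene_of_isoform=df.set_index("isoform_id")["gene_id"],
    )
    truth = GroundTruth(bins=bins, splice=splice, de_direction=dict(calls))
    return matrix, libs, calls, truth


# ---------------------------------------------------------------------------
# Network + annotation simulation
# ---------------------------------------------------------------------------


def simulate_network_and_annotations(
    cfg: SimulationConfig,
) -> tuple[nx.Graph, AnnotationSet, GroundTruth]:
    """Generate an interaction network and GMT with planted structure.

    The network contains a connected module organized in shells: a seed
    shell plus successive partner shells, each wired only to the previous
    shell, so iterative expansion grows by exactly one shell per round.  An
    unexpressed high-degree decoy hangs off the seed shell; noise edges
    connect only non-module genes.  The annotation holds one term from
    which most of the designated query is drawn (planted enrichment) unless
    ``planted_term_fraction`` is 0, in which case the query is uniform
    (a fully null configuration).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    universe = [f"G{i:05d}" for i in range(1, cfg.n_background_genes + 1)]

    module_size = sum(cfg.network_module_sizes)
    module_genes = list(rng.choice(universe, size=module_size, replace=False))
    shells: list[list[str]] = []
    pos = 0
    for size in cfg.network_module_sizes:
        shells.append(sorted(module_genes[pos : pos + size]))
        pos += size

    net = nx.Graph()
    net.add_nodes_from(universe)
    for prev, nxt in zip(shells, shells[1:]):
        for gene in nxt:
            partners = rng.choice(prev, size=min(2, len(prev)), replace=False)
            for p in partners:
                net.add_edge(gene, p, weight=float(rng.uniform(0.5, 2.0)))
    # connect the seed shell internally so it forms one component
    for g1, g2 in zip(shells[0], shells[0][1:]):
        net.add_edge(g1, g2, weight=float(rng.uniform(0.5, 2.0)))

    decoy = "UNEXPRESSED_HUB"
    for p in shells[0][: min(3, len(shells[0]))]:
        net.add_edge(decoy, p, weight=5.0)

    non_module = sorted(set(universe) - set(module_genes))
    added = 0
    attempts = 0
    while added < cfg.n_noise_edges and attempts < cfg.n_noise_edges * 20:
        attempts += 1
        a, b = rng.choice(non_module, size=2, replace=False)
        if net.has_edge(a, b):
            continue
        net.add_edge(a, b, weight=float(rng.uniform(0.2, 1.5)))
        added += 1

    # annotation: term_000 is the planted term
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    planted = sorted(rng.choice(universe, size=cfg.planted_term_size, replace=False))
    terms["term_000"] = ("planted process", frozenset(planted))
    for i in range(1, cfg.n_terms):
        size = int(rng.integers(cfg.term_size_range[0], cfg.term_size_range[1] + 1))
        genes = rng.choice(universe, size=size, replace=False)
        terms[f"term_{i:03d}"] = (f"random process {i}", frozenset(genes))
    ann = AnnotationSet(terms=terms, background=frozenset(universe))

    if cfg.planted_term_fraction > 0:
        n_in = int(round(cfg.planted_term_fraction * cfg.query_size))
        inside = list(rng.choice(planted, size=n_in, replace=False))
        outside_pool = sorted(set(universe) - set(planted))
        outside = list(
            rng.choice(outside_pool, size=cfg.query_size - n_in, replace=False)
        )
        query = sorted(inside + outside)
    else:
        query = sorted(rng.choice(universe, size=cfg.query_size, replace=False))

    truth = GroundTruth(
        module_shells=shells,
        unexpressed_decoy=decoy,
        planted_term_id="term_000",
        query=query,
    )
    return net, ann, truth


# ---------------------------------------------------------------------------
# Worked-example fixture
# ---------------------------------------------------------------------------

# Published FPKM values for selected genes in the developing mouse retina:
# skeletal-muscle troponin genes (all below the 1-FPKM expression threshold
# in every sample) and four genes around the P0 nuclear fraction, including
# the nuclear-only carboxylesterase Ces5a.  Samples are the E16 cytoplasmic
# extract, P0 cytoplasmic extract and P0 nuclear extract.
_WORKED_EXAMPLE = {
    # gene: (E16CE, P0CE, P0NE)
    "Tnnt3": (0.10, 0.11, 0.00),
    "Tnnt1": (0.94, 0.50, 0.50),
    "Tnni3k": (0.00, 0.02, 0.10),
    "Tnni2": (0.30, 0.21, 0.20),
    "Tnni1": (0.10, 0.90, 0.44),
    "Tnnc2": (0.00, 0.00, 0.10),
    "Tnnc1": (0.63, 0.95, 0.91),
    "Tnn": (0.00, 0.00, 0.10),
    "Ces5a": (0.073539, 0.420057, 161.0296),
    "Nrl": (0.558403, 15.8886, 6.104338),
    "Nr2e3": (0.008781, 28.08, 35.45415),
    "Gngt2": (10.06518, 91.92727, 22.08052),
}

MUSCLE_GENES = tuple(g for g in _WORKED_EXAMPLE if g.startswith("Tnn"))


def worked_example_fpkm() -> pd.DataFrame:
    """Gene-level worked-example FPKM table (E16CE, P0CE, P0NE columns)."""
    df = pd.DataFrame.from_dict(
        _WORKED_EXAMPLE, orient="index", columns=["E16CE", "P0CE", "P0NE"]
    )
    df.index.name = "gene_id"
    return df


def worked_example_matrix(include_housekeeping: bool = True) -> ExpressionMatrix:
    """Worked-example table as a single-isoform-per-gene expression matrix.

    Optionally appends a stably expressed Gapdh row (100 FPKM everywhere)
    so the housekeeping-normalized exact test can run on the fixture.
    """
    df = worked_example_fpkm().copy()
    if include_housekeeping:
        df.loc["Gapdh"] = [100.0, 100.0, 100.0]
    fpkm = df.copy()
    fpkm.index = [f"{g}.1" for g in df.index]
    fpkm.index.name = "isoform_id"
    genes = pd.Series(list(df.index), index=fpkm.index, name="gene_id")
    return ExpressionMatrix(fpkm=fpkm, gene_of_isoform=genes)
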