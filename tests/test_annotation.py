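"""Term enrichment and iterative network expansion."""

from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np
import pytest

from kineticsbin import (
    AnnotationSet,
    SimulationConfig,
    Thresholds,
    ValidationError,
    enrich,
    expand_gene_list,
    read_gmt,
    read_network,
    simulate_network_and_annotations,
    write_gmt,
    write_network,
)


def hypergeom_tail(k, M, K, n):
    """Oracle: P(overlap >= k) by exact summation of the hypergeometric mass."""
    total = comb(M, n)
    return float(
        sum(Fraction(comb(K, x) * comb(M - K, n - x), total) for x in range(k, min(K, n) + 1))
    )


def _annotation(terms, background):
    return AnnotationSet(
        terms={tid: (tid, frozenset(genes)) for tid, genes in terms.items()},
        background=frozenset(background),
    )


class TestEnrich:
    def test_full_overlap_is_minimum_p(self):
        bg = [f"g{i}" for i in range(100)]
        ann = _annotation(
            {"hit": bg[:10], "other1": bg[40:70], "other2": bg[70:90]}, bg
        )
        res = enrich(bg[:10], ann).set_index("term_id")
        assert res["p"].idxmin() == "hit"
        assert res.index[0] == "hit"

    def test_tail_sum_oracle(self):
        """Overlap 5 of list 10 vs term 10 in background 100 matches the
        exhaustive hypergeometric tail."""
        bg = [f"g{i}" for i in range(100)]
        term = bg[:10]
        query = bg[5:15]  # overlap 5
        ann = _annotation({"t": term}, bg)
        res = enrich(query, ann)
        assert res.iloc[0]["overlap"] == 5
        assert res.iloc[0]["p"] == pytest.approx(
            hypergeom_tail(5, 100, 10, 10), rel=1e-12
        )

    def test_random_overlaps_match_oracle(self):
        rng = np.random.default_rng(4)
        bg = [f"g{i}" for i in range(200)]
        for _ in range(30):
            term = list(rng.choice(bg, size=int(rng.integers(5, 50)), replace=False))
            query = list(rng.choice(bg, size=int(rng.integers(5, 40)), replace=False))
            ann = _annotation({"t": term}, bg)
            res = enrich(query, ann)
            k = len(set(term) & set(query))
            assert res.iloc[0]["p"] == pytest.approx(
                hypergeom_tail(k, 200, len(term), len(query)) if k else 1.0,
                rel=1e-10,
            )

    def test_ease_variant_is_more_conservative(self):
        bg = [f"g{i}" for i in range(100)]
        ann = _annotation({"t": bg[:10]}, bg)
        plain = enrich(bg[:10], ann).iloc[0]["p"]
        ease = enrich(bg[:10], ann, ease=True).iloc[0]["p"]
        assert ease > plain

    def test_bh_q_monotone_in_p_rank(self):
        rng = np.random.default_rng(9)
        bg = [f"g{i}" for i in range(300)]
        terms = {
            f"t{i}": list(rng.choice(bg, size=20, replace=False)) for i in range(25)
        }
        res = enrich(list(rng.choice(bg, 30, replace=False)), _annotation(terms, bg))
        sorted_by_p = res.sort_values("p")
        assert sorted_by_p["benjamini_q"].is_monotonic_increasing
        assert (res["benjamini_q"] >= res["p"] - 1e-15).all()

    def test_duplicated_annotation_keeps_q(self):
        """Duplicating every term under disjoint ids doubles the BH
        denominator and rank together, leaving q-values unchanged."""
        rng = np.random.default_rng(10)
        bg = [f"g{i}" for i in range(300)]
        terms = {
            f"t{i}": list(rng.choice(bg, size=20, replace=False)) for i in range(10)
        }
        query = list(rng.choice(bg, 30, replace=False))
        single = enrich(query, _annotation(terms, bg)).set_index("term_id")
        doubled_terms = dict(terms)
        doubled_terms.update({f"dup_{k}": v for k, v in terms.items()})
        doubled = enrich(query, _annotation(doubled_terms, bg)).set_index("term_id")
        for tid in terms:
            assert doubled.at[tid, "benjamini_q"] == pytest.approx(
                single.at[tid, "benjamini_q"]
            )

    def test_empty_query_rejected(self):
        ann = _annotation({"t": ["g1"]}, ["g1", "g2"])
        with pytest.raises(ValidationError):
            enrich([], ann)

    def test_query_outside_background_rejected(self):
        ann = _annotation({"t": ["g1"]}, ["g1", "g2"])
        with pytest.raises(ValidationError):
            enrich(["zz"], ann)

    def test_gmt_round_trip(self, tmp_path):
        ann = _annotation({"t1": ["g1", "g2"], "t2": ["g2", "g3"]}, [f"g{i}" for i in range(1, 5)])
        p = tmp_path / "x.gmt"
        write_gmt(ann, p)
        back = read_gmt(p, background=ann.background)
        assert {t: g for t, (_, g) in back.terms.items()} == {
            t: g for t, (_, g) in ann.terms.items()
        }


class TestExpand:
    def test_isolated_seed_converges_immediately(self):
        net = nx.Graph()
        net.add_nodes_from(["s1", "s2"])
        trace = expand_gene_list(["s1", "s2"], net, {"s1", "s2", "x"})
        assert trace.converged
        assert trace.iterations == 1
        assert trace.growth_iterations == 0
        assert trace.final_list == ["s1", "s2"]

    def test_star_network_hub_added_decoy_never(self):
        """Expressed hub joins; an unexpressed high-degree node never does."""
        net = nx.Graph()
        seeds = [f"s{i}" for i in range(5)]
        for s in seeds:
            net.add_edge("hub", s, weight=1.0)
            net.add_edge("decoy", s, weight=9.0)
        expressed = set(seeds) | {"hub"}
        trace = expand_gene_list(seeds, net, expressed, partners_per_round=5)
        assert "hub" in trace.final_list
        assert "decoy" not in trace.final_list
        # round 1 scores: decoy 45, hub 5 -- both candidates, one survives
        assert trace.rounds[0].candidates[0] == "decoy"
        assert trace.rounds[0].added == ["hub"]

    def test_seed_absent_from_network_warns_and_keeps(self, caplog):
        net = nx.Graph()
        net.add_edge("s1", "p1", weight=1.0)
        with caplog.at_level("WARNING"):
            trace = expand_gene_list(["s1", "ghost"], net, {"s1", "ghost", "p1"})
        assert "ghost" in trace.final_list
        assert any("absent from the network" in r.message for r in caplog.records)

    def test_order_invariance(self):
        """Result is independent of edge and seed input order."""
        rng = np.random.default_rng(13)
        edges = [
            (f"n{a}", f"n{b}", float(w))
            for a, b, w in zip(
                rng.integers(0, 30, 80), rng.integers(0, 30, 80), rng.uniform(0.1, 2, 80)
            )
            if a != b
        ]
        expressed = {f"n{i}" for i in range(30)}
        seeds = ["n1", "n2", "n3"]
        g1 = nx.Graph()
        for a, b, w in edges:
            g1.add_edge(a, b, weight=w)
        g2 = nx.Graph()
        for a, b, w in reversed(edges):
            g2.add_edge(a, b, weight=w)
        t1 = expand_gene_list(seeds, g1, expressed, partners_per_round=3)
        t2 = expand_gene_list(list(reversed(seeds)), g2, expressed, partners_per_round=3)
        assert t1.final_list == t2.final_list

    def test_monotone_growth_and_bound(self):
        cfg = SimulationConfig(seed=3)
        net, ann, truth = simulate_network_and_annotations(cfg)
        trace = expand_gene_list(truth.module_shells[0], net, ann.background)
        sizes = [len(r.input_list) for r in trace.rounds] + [len(trace.final_list)]
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))
        assert set(trace.final_list) <= set(trace.seed) | set(ann.background)

    def test_prefiltered_network_equivalent_on_planted_module(self):
        """Removing unexpressed genes from the network up front matches
        per-round filtering when candidates fit in the partner budget."""
        cfg = SimulationConfig(seed=5)
        net, ann, truth = simulate_network_and_annotations(cfg)
        expressed = set(ann.background)
        full = expand_gene_list(truth.module_shells[0], net, expressed)
        restricted = net.subgraph([n for n in net if n in expressed]).copy()
        pre = expand_gene_list(truth.module_shells[0], restricted, expressed)
        assert full.final_list == pre.final_list

    def test_network_round_trip_and_validation(self, tmp_path):
        net = nx.Graph()
        net.add_edge("a", "b", weight=1.5)
        net.add_edge("b", "c", weight=0.5)
        p = tmp_path / "net.tsv"
        write_network(net, p)
        back = read_network(p)
        assert set(back.edges) == set(net.edges)
        assert back["a"]["b"]["weight"] == 1.5
        p.write_text("gene_a\tgene_b\tweight\na\ta\t1.0\n")
        with pytest.raises(ValidationError, match="self-loop"):
            read_network(p)
        p.write_text("gene_a\tgene_b\tweight\na\tb\t1.0\nb\ta\t2.0\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_network(p)
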