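"""Term-level similarity: IC, MICA, Resnik, Relevance, Wang, HGS."""
from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from hecasd.ontology import OntologyError, RelationType
from hecasd.term_similarity import (
    WeightMode,
    WeightScheme,
    build_ic_table,
    edge_weight,
    graph_term_sim,
    mica,
    relevance_sim,
    resnik_sim,
    svalues,
)

from conftest import random_dag

WANG = WeightScheme.wang()
HGS = WeightScheme.hgs()


def naive_svalues(graph, focus, scheme):
    """Oracle: max product of edge weights over all rootward paths."""
    best = {focus: 1.0}

    def paths(term):
        yield [(term, 1.0)]
        for parent, rel in graph.parent_edges(term):
            w = edge_weight(graph, parent, rel, scheme)
            for tail in paths(parent):
                yield [(term, 1.0)] + [(t, w * p) for t, p in tail]

    for path in paths(focus):
        for term, product in path:
            if product > best.get(term, 0.0):
                best[term] = product
    return best


class TestICTable:
    @pytest.mark.parametrize(
        "term,pro,ic",
        [
            ("R", 1.0, 0.0),
            ("D", 0.2, -math.log(0.2)),
            ("B", 0.6, -math.log(0.6)),
        ],
    )
    def test_toy_values(self, toy_graph, toy_ic, term, pro, ic):
        assert toy_ic.pro[term] == pytest.approx(pro, abs=1e-12)
        assert toy_ic.ic[term] == pytest.approx(ic, abs=1e-12)

    def test_root_identity_and_monotonicity(self):
        rng = np.random.default_rng(7)
        graph = random_dag(rng, 25)
        table = build_ic_table(graph)
        assert table.pro[graph.root()] == 1.0
        assert table.ic[graph.root()] == 0.0
        for child in graph:
            for parent in graph.parents(child):
                assert table.pro[parent] >= table.pro[child]
                assert table.ic[child] == pytest.approx(-math.log(table.pro[child]))


class TestICMeasures:
    def test_mica_cases(self, toy_graph, toy_ic):
        assert mica(toy_graph, toy_ic, "C", "B") == "B"
        assert mica(toy_graph, toy_ic, "A", "B") == "R"
        assert mica(toy_graph, toy_ic, "D", "D") == "D"

    def test_resnik_values(self, toy_graph, toy_ic):
        assert resnik_sim(toy_graph, toy_ic, "A", "B") == 0.0
        assert resnik_sim(toy_graph, toy_ic, "C", "B") == pytest.approx(
            -math.log(0.6), abs=1e-9
        )
        for t in toy_graph:
            assert resnik_sim(toy_graph, toy_ic, t, t) == pytest.approx(toy_ic.ic[t])

    def test_resnik_bounded_by_own_ic(self, toy_graph, toy_ic):
        for t1, t2 in itertools.combinations(sorted(toy_graph.terms), 2):
            assert resnik_sim(toy_graph, toy_ic, t1, t2) <= min(
                toy_ic.ic[t1], toy_ic.ic[t2]
            ) + 1e-12

    def test_relevance_hand_value(self, toy_graph, toy_ic):
        # MICA(C,B)=B: 2*IC(B)*(1-0.6) / (IC(C)+IC(B))
        expected = 2 * toy_ic.ic["B"] * 0.4 / (toy_ic.ic["C"] + toy_ic.ic["B"])
        assert relevance_sim(toy_graph, toy_ic, "C", "B") == pytest.approx(
            expected, abs=1e-9
        )
        assert expected == pytest.approx(0.2863, abs=5e-4)

    def test_relevance_root_conventions(self, toy_graph, toy_ic):
        assert relevance_sim(toy_graph, toy_ic, "A", "B") == 0.0  # root MICA
        assert relevance_sim(toy_graph, toy_ic, "R", "R") == 0.0  # 0/0 convention

    def test_symmetry(self, toy_graph, toy_ic):
        for t1, t2 in itertools.combinations(sorted(toy_graph.terms), 2):
            assert relevance_sim(toy_graph, toy_ic, t1, t2) == relevance_sim(
                toy_graph, toy_ic, t2, t1
            )
            assert resnik_sim(toy_graph, toy_ic, t1, t2) == resnik_sim(
                toy_graph, toy_ic, t2, t1
            )


class TestEdgeWeights:
    def test_wang_constants(self, toy_graph):
        assert edge_weight(toy_graph, "R", RelationType.IS_A, WANG) == 0.8
        assert edge_weight(toy_graph, "R", RelationType.PART_OF, WANG) == 0.6

    def test_hgs_child_count_penalty(self, toy_graph):
        # C has 1 child, R has 2
        assert edge_weight(toy_graph, "C", RelationType.IS_A, HGS) == pytest.approx(
            1 / 1.67 + 0.4, abs=1e-9
        )
        assert edge_weight(toy_graph, "R", RelationType.IS_A, HGS) == pytest.approx(
            1 / 2.67 + 0.4, abs=1e-9
        )
        assert edge_weight(toy_graph, "R", RelationType.PART_OF, HGS) < edge_weight(
            toy_graph, "R", RelationType.IS_A, HGS
        )

    def test_childless_parent_is_an_error(self, toy_graph):
        with pytest.raises(OntologyError):
            edge_weight(toy_graph, "D", RelationType.IS_A, HGS)

    def test_weights_below_one(self):
        rng = np.random.default_rng(11)
        graph = random_dag(rng, 40)
        for scheme in (WANG, HGS):
            for _, parent, rel in graph.edges:
                assert 0.0 < edge_weight(graph, parent, rel, scheme) < 1.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(OntologyError):
            WeightScheme(w_isa=1.5)
        with pytest.raises(OntologyError):
            WeightScheme.hgs(c=0.0)


class TestSValues:
    def test_chain_hand_recursion(self, chain_graph):
        s = svalues(chain_graph, "B", WANG)
        assert s.svalue == pytest.approx({"B": 1.0, "A": 0.8, "R": 0.64})
        assert s.sv == pytest.approx(2.44)

    def test_toy_multipath_max(self, toy_graph):
        s = svalues(toy_graph, "D", WANG).svalue
        assert s["A"] == pytest.approx(0.64)
        assert s["B"] == pytest.approx(0.48)
        assert s["R"] == pytest.approx(0.512)  # max(0.8*0.64, 0.8*0.48)

    def test_focus_always_one(self, toy_graph):
        for scheme in (WANG, HGS):
            for t in toy_graph:
                assert svalues(toy_graph, t, scheme).svalue[t] == 1.0

    def test_ancestors_never_exceed_their_best_child(self):
        """S(parent) = max_u w * S(u) < max_u S(u): every ancestor's S-value
        is strictly below its best sub-DAG child's (weights are < 1), so the
        focus term is the unique maximum."""
        rng = np.random.default_rng(13)
        for _ in range(10):
            graph = random_dag(rng, 25)
            for scheme in (WANG, HGS):
                for focus in sorted(graph.terms)[:5]:
                    sub = graph.induced_subdag(focus)
                    s = svalues(graph, focus, scheme).svalue
                    children_in = {}
                    for child, parent, _ in sub.edges:
                        children_in.setdefault(parent, []).append(child)
                    for parent, kids in children_in.items():
                        assert s[parent] < max(s[k] for k in kids)
                    assert max(s, key=s.get) == focus

    def test_dp_matches_naive_path_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            graph = random_dag(rng, int(rng.integers(5, 31)))
            focus = sorted(graph.terms)[int(rng.integers(len(graph)))]
            for scheme in (WANG, HGS):
                dp = svalues(graph, focus, scheme).svalue
                oracle = naive_svalues(graph, focus, scheme)
                assert dp.keys() == oracle.keys()
                for term in dp:
                    assert dp[term] == pytest.approx(oracle[term], abs=1e-12)


class TestGraphTermSim:
    def test_chain_hand_value(self, chain_graph):
        assert graph_term_sim(chain_graph, "A", "B", WANG) == pytest.approx(
            (0.8 + 1 + 0.64 + 0.8) / (1.8 + 2.44), abs=1e-12
        )

    def test_toy_hand_value(self, chain_graph, toy_graph):
        assert graph_term_sim(toy_graph, "C", "D", WANG) == pytest.approx(
            5.472 / 6.472, abs=1e-9
        )

    def test_identity_and_range(self, toy_graph):
        for scheme in (WANG, HGS):
            for t1 in toy_graph:
                for t2 in toy_graph:
                    sim = graph_term_sim(toy_graph, t1, t2, scheme)
                    assert 0.0 <= sim <= 1.0
                    if t1 == t2:
                        assert sim == pytest.approx(1.0, abs=1e-12)
                    else:
                        assert sim < 1.0 - 1e-9
                    assert sim == graph_term_sim(toy_graph, t2, t1, scheme)

    def test_hgs_reduces_to_wang_on_chains(self):
        """With child counts pinned at 1, matched d constants make HGS = Wang."""
        from hecasd.ontology import OntologyGraph

        names = [f"C{i}" for i in range(6)]
        edges = [
            (names[i], names[i - 1], RelationType.IS_A if i % 2 else RelationType.PART_OF)
            for i in range(1, 6)
        ]
        chain = OntologyGraph(names, edges)
        base = 1.0 / (0.67 + 1)
        matched = WeightScheme.hgs(d_isa=0.8 - base, d_partof=0.6 - base)
        for t1 in names:
            for t2 in names:
                assert graph_term_sim(chain, t1, t2, matched) == pytest.approx(
                    graph_term_sim(chain, t1, t2, WANG), abs=1e-12
                )
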