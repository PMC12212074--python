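"""Coverage classification, Hi-C Graph construction and KL bipartition."""

import itertools

import networkx as nx
import numpy as np
import pytest

from haplink.graph import PLUS
from haplink.io import HiCPairRecord, HomologyMatch
from haplink.match_graph import build_match_graph, classify_edges
from haplink.phase import (
    AMBIGUOUS,
    HAP1,
    HAP2,
    HOMOZYGOUS,
    UNIQUE,
    Partition,
    assign_short_nodes,
    build_hic_graph,
    classify_nodes_by_coverage,
    cut_weight,
    kernighan_lin,
    kl_bipartition,
    qualifying_pairs,
    split_components,
)

from conftest import chain_graph, make_graph


def pair(pid, n1, n2, mapq=60, n_equiv=1):
    return [
        HiCPairRecord(pid, 1, n1, 0, mapq, n_equiv),
        HiCPairRecord(pid, 2, n2, 0, mapq, n_equiv),
    ]


def hap_match(a, b, span=400_000):
    return HomologyMatch(a, b, 0, span, 0, span, span, 0.99)


def exhaustive_min_cut(w):
    """Brute-force minimum balanced cut (side sizes differ by at most 1)."""
    n = w.shape[0]
    sizes = (n // 2,) if n % 2 == 0 else (n // 2, n // 2 + 1)
    best = np.inf
    for sz in sizes:
        for comb in itertools.combinations(range(n), sz):
            s = -np.ones(n)
            s[list(comb)] = 1
            best = min(best, cut_weight(w, s))
    return best


class TestCoverageClassification:
    def _graph(self):
        # five 80 kb nodes near 30x fix the component baseline's median
        g = chain_graph([f"b{i}" for i in range(5)], length=80_000, coverage=30.0)
        return g

    @pytest.mark.parametrize(
        "cov,expected",
        [(13.0, UNIQUE), (11.0, AMBIGUOUS), (60.0, HOMOZYGOUS)],
    )
    def test_large_node_rules_against_component_baseline(self, cov, expected):
        from haplink.graph import Node

        g = self._graph()
        g.add_node(Node("q", 80_000, cov))
        g.add_edge(("b4", PLUS), ("q", PLUS))
        assert classify_nodes_by_coverage(g)["q"] == expected

    @pytest.mark.parametrize(
        "cov,expected", [(21.0, UNIQUE), (20.0, AMBIGUOUS), (40.0, AMBIGUOUS)]
    )
    def test_short_node_uses_tighter_band(self, cov, expected):
        from haplink.graph import Node

        g = self._graph()
        g.add_node(Node("q", 40_000, cov))
        g.add_edge(("b4", PLUS), ("q", PLUS))
        assert classify_nodes_by_coverage(g)["q"] == expected

    def test_all_zero_coverage_is_an_error(self):
        g = chain_graph(["a", "b"], coverage=0.0)
        with pytest.raises(ValueError):
            classify_nodes_by_coverage(g)


class TestHiCGraph:
    def test_ambiguous_side_contributes_nothing(self):
        g = make_graph([("A", 300_000), ("B", 300_000)])
        mg = build_match_graph(g, [])
        pairs = pair("p1", "A", "B", mapq=0)
        h = build_hic_graph(g, mg, pairs)
        assert not h.has_edge("A", "B")
        assert qualifying_pairs(pairs) == {}

    def test_multimapping_side_contributes_nothing(self):
        g = make_graph([("A", 300_000), ("B", 300_000)])
        pairs = pair("p1", "A", "B", n_equiv=2)
        assert qualifying_pairs(pairs) == {}

    def test_qualifying_pairs_count_as_weight(self):
        g = make_graph([("A", 300_000), ("B", 300_000)])
        mg = build_match_graph(g, [])
        pairs = [r for i in range(7) for r in pair(f"p{i}", "A", "B")]
        h = build_hic_graph(g, mg, pairs)
        assert h["A"]["B"]["weight"] == 7.0
        assert h["A"]["B"]["hic_count"] == 7

    def test_homolog_pair_gets_large_negative_weight(self):
        g = make_graph([(n, 900_000) for n in "ABCD"])
        mg = classify_edges(build_match_graph(g, [hap_match("A", "B")]), g)
        pairs = [r for i in range(40) for r in pair(f"c{i}", "C", "D")]
        pairs += [r for i in range(5) for r in pair(f"x{i}", "A", "B")]
        h = build_hic_graph(g, mg, pairs)
        assert h["A"]["B"]["weight"] == -400.0  # -10 * max weight 40
        assert h["A"]["B"]["forced_negative"]

    def test_short_nodes_and_repeat_incident_nodes_excluded(self):
        g = make_graph([("A", 100_000), ("B", 900_000), ("C", 900_000), ("D", 900_000),
                        ("E", 900_000), ("R", 900_000), ("S", 900_000)])
        # R-S is second best at both endpoints -> repeat edge
        ms = [hap_match("B", "C", 500_000), hap_match("D", "E", 500_000),
              HomologyMatch("R", "B", 0, 210_000, 0, 210_000, 210_000, 0.99),
              HomologyMatch("S", "D", 0, 210_000, 0, 210_000, 210_000, 0.99),
              HomologyMatch("R", "S", 0, 205_000, 0, 205_000, 205_000, 0.99)]
        mg = classify_edges(build_match_graph(g, ms), g)
        assert mg.edge("R", "S").klass == "repeat"
        pairs = [r for i in range(3) for r in pair(f"p{i}", "R", "S")]
        pairs += pair("q", "A", "B")
        h = build_hic_graph(g, mg, pairs)
        assert "R" not in h and "S" not in h
        assert "A" not in h  # below the 200 kb node threshold

    def test_self_links_dropped(self):
        g = make_graph([("A", 300_000), ("B", 300_000)])
        mg = build_match_graph(g, [])
        h = build_hic_graph(g, mg, pair("p1", "A", "A"))
        assert h.number_of_edges() == 0


class TestSplitComponents:
    def test_cross_component_hic_edge_discarded(self):
        g = make_graph([("A", 300_000), ("B", 300_000), ("C", 300_000), ("D", 300_000)])
        g.add_edge(("A", PLUS), ("B", PLUS))
        g.add_edge(("C", PLUS), ("D", PLUS))
        mg = build_match_graph(g, [])
        comps = split_components(g, mg)
        assert comps == [{"A", "B"}, {"C", "D"}]
        pairs = pair("p1", "A", "C")  # spurious cross-chromosome link
        h = build_hic_graph(g, mg, pairs, components=comps)
        assert not h.has_edge("A", "C")

    def test_haplotype_match_edge_merges_components(self):
        g = make_graph([("X", 900_000), ("Y", 900_000)])
        mg = classify_edges(build_match_graph(g, [hap_match("X", "Y")]), g)
        assert split_components(g, mg) == [{"X", "Y"}]

    def test_empty_graph(self):
        g = make_graph([])
        assert split_components(g, build_match_graph(g, [])) == []


class TestKernighanLin:
    def test_two_triangles_with_weak_bridge(self):
        # planted optimum: cut the single weight-1 bridge
        w = np.zeros((6, 6))
        for (a, b) in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]:
            w[a, b] = w[b, a] = 5.0
        w[2, 3] = w[3, 2] = 1.0
        assert exhaustive_min_cut(w) == 1.0
        sides, cut = kernighan_lin(w, restarts=50, rng=np.random.default_rng(0))
        assert cut == 1.0
        assert len({tuple(sides[:3]), tuple(sides[3:])}) == 2

    def test_single_node(self):
        sides, cut = kernighan_lin(np.zeros((1, 1)), restarts=5)
        assert cut == 0.0 and len(sides) == 1

    def test_forced_negative_pair_separated(self):
        w = np.array([[0.0, -10.0], [-10.0, 0.0]])
        sides, cut = kernighan_lin(w, restarts=5, rng=np.random.default_rng(0))
        assert cut == -10.0
        assert sides[0] != sides[1]

    def test_never_worse_than_random_initialisations(self, rng):
        n = 10
        w = np.zeros((n, n))
        for a in range(n):
            for b in range(a + 1, n):
                w[a, b] = w[b, a] = rng.normal(0, 3)
        _, cut = kernighan_lin(w, restarts=100, rng=np.random.default_rng(7))
        for _ in range(200):
            s = np.ones(n)
            s[rng.permutation(n)[: n // 2]] = -1
            assert cut <= cut_weight(w, s) + 1e-9

    def test_label_swap_symmetry(self, rng):
        n = 8
        w = rng.normal(0, 2, (n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        s = np.ones(n)
        s[:4] = -1
        assert cut_weight(w, s) == pytest.approx(cut_weight(w, -s))

    def test_matches_exhaustive_optimum_on_small_graphs(self):
        hit = 0
        for i in range(20):
            rng = np.random.default_rng(100 + i)
            n = int(rng.integers(4, 11))
            w = np.zeros((n, n))
            for a in range(n):
                for b in range(a + 1, n):
                    if rng.random() < 0.6:
                        w[a, b] = w[b, a] = rng.normal(0, 5)
            _, cut = kernighan_lin(w, restarts=200, rng=rng)
            opt = exhaustive_min_cut(w)
            assert cut >= opt - 1e-9  # never below the true optimum
            hit += abs(cut - opt) < 1e-9
        assert hit >= 19

    def test_deterministic_given_seed(self):
        g = make_graph([(f"n{i}", 300_000) for i in range(9)])
        h = nx.Graph()
        rng = np.random.default_rng(3)
        names = sorted(g.nodes)
        h.add_nodes_from(names)
        for a in range(9):
            for b in range(a + 1, 9):
                h.add_edge(names[a], names[b], weight=float(rng.normal(0, 2)))
        p1 = kl_bipartition(h, names, restarts=50, seed=11)
        p2 = kl_bipartition(h, names, restarts=50, seed=11)
        assert p1.assignment == p2.assignment
        assert p1.cut_weight == p2.cut_weight


class TestShortNodeAssignment:
    def _setup(self, counts):
        g = make_graph(
            [("L1", 300_000), ("L2", 300_000), ("s", 50_000)]
        )
        part = Partition(assignment={"L1": HAP1, "L2": HAP2})
        pairs = []
        c1, c2 = counts
        for i in range(c1):
            pairs += pair(f"a{i}", "s", "L1")
        for i in range(c2):
            pairs += pair(f"b{i}", "s", "L2")
        return g, part, pairs

    @pytest.mark.parametrize(
        "counts,expected",
        [((5, 2), HAP1), ((4, 2), "unassigned"), ((3, 0), HAP1), ((0, 0), "unassigned"),
         ((2, 5), HAP2)],
    )
    def test_majority_rule(self, counts, expected):
        g, part, pairs = self._setup(counts)
        assign_short_nodes(part, pairs, g)
        assert part.assignment["s"] == expected

    def test_homozygous_candidates_stay_homozygous(self):
        g, part, pairs = self._setup((5, 0))
        assign_short_nodes(part, pairs, g, homozygous={"s"})
        assert part.assignment["s"] == HOMOZYGOUS
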