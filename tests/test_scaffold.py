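"""End-window link weights, bonuses, mutual-best joins and telomere rescue."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haplink.graph import MINUS, PLUS
from haplink.io import HiCPairRecord, HomologyMatch
from haplink.paths import HaplotypePath
from haplink.scaffold import (
    PREFIX,
    SUFFIX,
    JoinCandidate,
    apply_bonuses,
    apply_joins,
    compute_link_weights,
    filter_pairs_for_scaffolding,
    graph_distance_between_nodes,
    induced_links,
    layout_path,
    select_joins,
    telomere_rescue,
)

from conftest import chain_graph, make_graph


def rec(pid, side, node, pos=0, mapq=60, n_equiv=1):
    return HiCPairRecord(pid, side, node, pos, mapq, n_equiv)


class TestFilter:
    def test_side_with_six_mappings_dropped(self):
        pairs = [rec("p", 1, f"A{i}", n_equiv=6) for i in range(6)] + [rec("p", 2, "B")]
        assert filter_pairs_for_scaffolding(pairs) == {}

    def test_shared_node_dropped(self):
        pairs = [rec("p", 1, "A"), rec("p", 1, "C", n_equiv=2), rec("p", 2, "A", n_equiv=1)]
        pairs[0] = rec("p", 1, "A", n_equiv=2)
        assert filter_pairs_for_scaffolding(pairs) == {}

    def test_multimappers_within_cap_kept(self):
        pairs = (
            [rec("p", 1, "A", n_equiv=2), rec("p", 1, "B", n_equiv=2)]
            + [rec("p", 2, f"C{i}", n_equiv=3) for i in range(3)]
        )
        kept = filter_pairs_for_scaffolding(pairs)
        assert set(kept) == {"p"}

    @given(st.integers(1, 5), st.integers(1, 5))
    @settings(max_examples=30, deadline=None)
    def test_induced_link_weights_sum_to_one(self, m1, m2):
        s1 = [rec("p", 1, f"A{i}", n_equiv=m1) for i in range(m1)]
        s2 = [rec("p", 2, f"B{i}", n_equiv=m2) for i in range(m2)]
        links = induced_links(s1, s2)
        assert len(links) == m1 * m2
        assert sum(w for _, _, w in links) == pytest.approx(1.0, abs=1e-12)


def two_path_setup(n_nodes=4, length=1_000_000):
    """Two disjoint linear paths p1, p2 with their nodes chained in the graph."""
    ids1 = [f"a{i}" for i in range(n_nodes)]
    ids2 = [f"b{i}" for i in range(n_nodes)]
    g = make_graph([(i, length) for i in ids1 + ids2])
    for ids in (ids1, ids2):
        for x, y in zip(ids, ids[1:]):
            g.add_edge((x, PLUS), (y, PLUS))
    p1 = HaplotypePath("p1", [(i, PLUS) for i in ids1], "hap1")
    p2 = HaplotypePath("p2", [(i, PLUS) for i in ids2], "hap1")
    return g, p1, p2, ids1, ids2


class TestLinkWeights:
    def test_multiplicity_two_by_three_contributes_one_sixth(self):
        g, p1, p2, ids1, ids2 = two_path_setup()
        from haplink.graph import Node

        g.add_node(Node("offpath", 1_000_000, 30.0))
        layouts = {p.name: layout_path(p, g) for p in (p1, p2)}
        pairs = [
            rec("p", 1, "a3", 900_000, n_equiv=2),  # p1 suffix window
            rec("p", 1, "a0", 0, n_equiv=2),        # p1 prefix window
            rec("p", 2, "b0", 100, n_equiv=3),      # p2 prefix window
            rec("p", 2, "b3", 900_000, n_equiv=3),  # p2 suffix window
            rec("p", 2, "offpath", 0, n_equiv=3),   # not on any path
        ]
        retained = filter_pairs_for_scaffolding(pairs)
        cands = compute_link_weights(layouts, retained)
        # every induced link lands in exactly one end-pair: each weighs 1/6
        for e1 in (PREFIX, SUFFIX):
            for e2 in (PREFIX, SUFFIX):
                c = cands[tuple(sorted([("p1", e1), ("p2", e2)]))]
                assert c.primary == pytest.approx(1 / 6)
                assert c.secondary == 0.0

    def test_unique_pairs_count_fully_in_both_weights(self):
        g, p1, p2, ids1, ids2 = two_path_setup()
        layouts = {p.name: layout_path(p, g) for p in (p1, p2)}
        pairs = []
        for i in range(10):
            pairs += [rec(f"p{i}", 1, "a3", 900_000), rec(f"p{i}", 2, "b0", 100)]
        cands = compute_link_weights(layouts, filter_pairs_for_scaffolding(pairs))
        c = cands[(("p1", SUFFIX), ("p2", PREFIX))]
        assert c.primary == pytest.approx(10.0)
        assert c.secondary == pytest.approx(10.0)

    def test_double_multimappers_add_quarter_each(self):
        g, p1, p2, ids1, ids2 = two_path_setup()
        layouts = {p.name: layout_path(p, g) for p in (p1, p2)}
        pairs = []
        for i in range(4):
            pairs += [
                rec(f"p{i}", 1, "a3", 900_000, n_equiv=2),
                rec(f"p{i}", 1, "a0", 0, n_equiv=2),
                rec(f"p{i}", 2, "b0", 100, n_equiv=2),
                rec(f"p{i}", 2, "b3", 900_000, n_equiv=2),
            ]
        cands = compute_link_weights(layouts, filter_pairs_for_scaffolding(pairs))
        c = cands[(("p1", SUFFIX), ("p2", PREFIX))]
        assert c.primary == pytest.approx(4 * 0.25)
        assert c.secondary == 0.0

    def test_window_is_half_path_when_short(self):
        g, p1, p2, *_ = two_path_setup(n_nodes=4, length=1_000_000)
        lay = layout_path(p1, g, window_cap=5_000_000)
        assert lay.length == 4_000_000
        assert lay.window_len == 2_000_000
        assert lay.end_interval(PREFIX) == (0, 2_000_000)
        assert lay.end_interval(SUFFIX) == (2_000_000, 4_000_000)

    def test_reverse_oriented_step_projects_mirrored(self):
        g, p1, p2, *_ = two_path_setup()
        p_rev = HaplotypePath("r", [("a0", MINUS)], "hap1")
        lay = layout_path(p_rev, g)
        from haplink.scaffold import project_position

        assert project_position(lay, "a0", 0) == [999_999]


class TestBonuses:
    def test_proximity_through_small_tangle_triples_weight(self):
        g, p1, p2, ids1, ids2 = two_path_setup()
        from haplink.graph import Node

        g.add_node(Node("tangle", 100_000, 120.0))
        g.add_edge(("a3", PLUS), ("tangle", PLUS))
        g.add_edge(("tangle", PLUS), ("b0", PLUS))
        layouts = {p.name: layout_path(p, g) for p in (p1, p2)}
        key = (("p1", SUFFIX), ("p2", PREFIX))
        cands = {key: JoinCandidate(*key, primary=10.0, secondary=4.0)}
        apply_bonuses(cands, g, layouts)
        assert cands[key].primary == pytest.approx(30.0)
        assert cands[key].secondary == pytest.approx(12.0)
        assert cands[key].bonuses == {"graph_proximity"}

    def test_distant_ends_get_no_proximity_bonus(self):
        g, p1, p2, *_ = two_path_setup()
        from haplink.graph import Node

        g.add_node(Node("big", 600_000, 30.0))
        g.add_edge(("a3", PLUS), ("big", PLUS))
        g.add_edge(("big", PLUS), ("b0", PLUS))
        layouts = {p.name: layout_path(p, g) for p in (p1, p2)}
        key = (("p1", SUFFIX), ("p2", PREFIX))
        cands = {key: JoinCandidate(*key, primary=10.0)}
        apply_bonuses(cands, g, layouts)
        assert cands[key].primary == pytest.approx(10.0)

    def _homology_setup(self):
        # p3 is an unbroken homolog; p1/p2 are the two halves of the other
        # haplotype, each homologous to a half of p3
        ids1 = ["a0", "a1"]
        ids2 = ["a2", "a3"]
        ids3 = ["c0", "c1", "c2", "c3"]
        g = make_graph([(i, 1_000_000) for i in ids1 + ids2 + ids3])
        p1 = HaplotypePath("p1", [(i, PLUS) for i in ids1], "hap1")
        p2 = HaplotypePath("p2", [(i, PLUS) for i in ids2], "hap1")
        p3 = HaplotypePath("p3", [(i, PLUS) for i in ids3], "hap2")
        matches = [
            HomologyMatch(f"a{i}", f"c{i}", 0, 900_000, 0, 900_000, 900_000, 0.99)
            for i in range(4)
        ]
        layouts = {p.name: layout_path(p, g) for p in (p1, p2, p3)}
        return g, layouts, matches

    def test_homology_to_adjacent_positions_on_third_path_x5(self):
        g, layouts, matches = self._homology_setup()
        key = (("p1", SUFFIX), ("p2", PREFIX))
        cands = {key: JoinCandidate(*key, primary=2.0)}
        apply_bonuses(cands, g, layouts, matches)
        assert cands[key].bonuses == {"homology"}
        assert cands[key].primary == pytest.approx(10.0)

    def test_both_bonuses_compound_to_fifteen(self):
        g, layouts, matches = self._homology_setup()
        g.add_edge(("a1", PLUS), ("a2", PLUS))  # adjacent in the graph
        key = (("p1", SUFFIX), ("p2", PREFIX))
        cands = {key: JoinCandidate(*key, primary=2.0)}
        apply_bonuses(cands, g, layouts, matches)
        assert cands[key].bonuses == {"graph_proximity", "homology"}
        assert cands[key].primary == pytest.approx(30.0)

    def test_graph_distance_helper(self):
        g = chain_graph(["x", "m", "y"], length=200_000)
        assert graph_distance_between_nodes(g, "x", "y", 500_000) == 200_000
        assert graph_distance_between_nodes(g, "x", "m", 500_000) == 0
        assert graph_distance_between_nodes(g, "x", "y", 100_000) is None


def cand(e1, e2, primary, secondary=0.0):
    return JoinCandidate(e1, e2, primary, secondary)


class TestSelectJoins:
    def _paths(self, names, telo=()):
        out = []
        for n in names:
            p = HaplotypePath(n, [(n + "_n", PLUS)], "hap1")
            if (n, "left") in telo:
                p.telo_left = True
            if (n, "right") in telo:
                p.telo_right = True
            out.append(p)
        return out

    def test_mutual_clear_best_join_accepted(self):
        paths = self._paths(["p1", "p2", "p3", "p4"])
        cands = {
            (("p1", SUFFIX), ("p2", PREFIX)): cand(("p1", SUFFIX), ("p2", PREFIX), 10.0),
            (("p1", SUFFIX), ("p3", PREFIX)): cand(("p1", SUFFIX), ("p3", PREFIX), 5.0),
            (("p2", PREFIX), ("p4", SUFFIX)): cand(("p2", PREFIX), ("p4", SUFFIX), 2.0),
        }
        joins = select_joins(cands, paths)
        assert [(j.end1, j.end2) for j in joins] == [(("p1", SUFFIX), ("p2", PREFIX))]

    def test_insufficient_margin_rejected(self):
        paths = self._paths(["p1", "p2", "p3"])
        cands = {
            (("p1", SUFFIX), ("p2", PREFIX)): cand(("p1", SUFFIX), ("p2", PREFIX), 10.0),
            (("p1", SUFFIX), ("p3", PREFIX)): cand(("p1", SUFFIX), ("p3", PREFIX), 7.0),
        }
        assert select_joins(cands, paths) == []  # 10 < 1.5 * 7

    def test_telomeric_end_never_extended(self):
        paths = self._paths(["p1", "p2"], telo={("p1", "right")})
        cands = {
            (("p1", SUFFIX), ("p2", PREFIX)): cand(("p1", SUFFIX), ("p2", PREFIX), 50.0),
        }
        assert select_joins(cands, paths) == []

    def test_secondary_weights_used_when_primary_yields_nothing(self):
        paths = self._paths(["p1", "p2", "p3"])
        cands = {
            (("p1", SUFFIX), ("p2", PREFIX)): cand(("p1", SUFFIX), ("p2", PREFIX), 10.0, 9.0),
            (("p1", SUFFIX), ("p3", PREFIX)): cand(("p1", SUFFIX), ("p3", PREFIX), 8.0, 1.0),
        }
        joins = select_joins(cands, paths)
        assert [(j.end1, j.end2) for j in joins] == [(("p1", SUFFIX), ("p2", PREFIX))]

    def test_no_circular_scaffolds(self):
        paths = self._paths(["p1", "p2"])
        cands = {
            (("p1", SUFFIX), ("p2", PREFIX)): cand(("p1", SUFFIX), ("p2", PREFIX), 10.0),
            (("p1", PREFIX), ("p2", SUFFIX)): cand(("p1", PREFIX), ("p2", SUFFIX), 10.0),
        }
        joins = select_joins(cands, paths)
        assert len(joins) == 1  # the second join would close a circle

    def test_each_end_used_at_most_once(self):
        paths = self._paths(["p1", "p2", "p3"])
        cands = {
            (("p1", SUFFIX), ("p2", PREFIX)): cand(("p1", SUFFIX), ("p2", PREFIX), 100.0),
            (("p3", SUFFIX), ("p2", PREFIX)): cand(("p3", SUFFIX), ("p2", PREFIX), 1.0),
        }
        joins = select_joins(cands, paths)
        ends = [e for j in joins for e in (j.end1, j.end2)]
        assert len(ends) == len(set(ends))


class TestApplyJoins:
    def test_chain_merge_with_gap_and_orientation(self):
        p1 = HaplotypePath("p1", [("a", PLUS)], "hap1", True, False)
        p2 = HaplotypePath("p2", [("b", PLUS)], "hap1", False, True)
        joins = [JoinCandidate(("p1", SUFFIX), ("p2", PREFIX))]
        (s,) = apply_joins([p1, p2], joins)
        assert s.node_steps() == [("a", PLUS), ("b", PLUS)]
        assert [g.reason for g in s.gaps()] == ["scaffold_join"]
        assert s.telo_left and s.telo_right

    def test_suffix_suffix_join_reverses_second_path(self):
        p1 = HaplotypePath("p1", [("a", PLUS)], "hap1")
        p2 = HaplotypePath("p2", [("b", PLUS)], "hap1")
        joins = [JoinCandidate(("p1", SUFFIX), ("p2", SUFFIX))]
        (s,) = apply_joins([p1, p2], joins)
        assert s.node_steps() == [("a", PLUS), ("b", MINUS)]

    def test_rdna_tagged_flanks_name_the_gap(self):
        p1 = HaplotypePath("p1", [("a", PLUS)], "hap1")
        p2 = HaplotypePath("p2", [("b", PLUS)], "hap1")
        joins = [JoinCandidate(("p1", SUFFIX), ("p2", PREFIX))]
        (s,) = apply_joins([p1, p2], joins, rdna_nodes={"a", "b"})
        assert [g.reason for g in s.gaps()] == ["rdna_like"]

    def test_mirror_symmetry_under_global_reversal(self):
        p1 = HaplotypePath("p1", [("a", PLUS), ("b", PLUS)], "hap1")
        p2 = HaplotypePath("p2", [("c", PLUS)], "hap1")
        joins = [JoinCandidate(("p1", SUFFIX), ("p2", PREFIX))]
        (fwd,) = apply_joins([p1, p2], joins)
        rjoins = [JoinCandidate(("p1", PREFIX), ("p2", SUFFIX))]
        (rev,) = apply_joins([p1.reversed(), p2.reversed()], rjoins)
        assert rev.node_steps() == [(n, MINUS if o == PLUS else PLUS)
                                    for (n, o) in reversed(fwd.node_steps())]


class TestTelomereRescue:
    def _setup(self, stub_dist_nodes=(), extra_big=False):
        # component: p1 is T2T hap1; p2 (hap2) lost its right telomere; pt is
        # a small telomeric stub near p2's open end
        ids1 = ["a0", "a1", "a2"]
        ids2 = ["b0", "b1", "b2"]
        nodes = [(i, 2_000_000) for i in ids1 + ids2] + [("t", 300_000)]
        nodes += [(i, 150_000) for i in stub_dist_nodes]
        if extra_big:
            nodes.append(("huge", 2_000_000))
        g = make_graph(nodes)
        for ids in (ids1, ids2):
            for x, y in zip(ids, ids[1:]):
                g.add_edge((x, PLUS), (y, PLUS))
        chain = ["b2", *stub_dist_nodes, "t"]
        for x, y in zip(chain, chain[1:]):
            g.add_edge((x, PLUS), (y, PLUS))
        g.add_edge(("a0", PLUS), ("b0", PLUS))  # keep one component
        if extra_big:
            g.add_edge(("huge", PLUS), ("b0", PLUS))
        g.node("a0").telo_start = True
        g.node("a2").telo_end = True
        g.node("b0").telo_start = True
        g.node("t").telo_end = True
        p1 = HaplotypePath("p1", [(i, PLUS) for i in ids1], "hap1", True, True)
        p2 = HaplotypePath("p2", [(i, PLUS) for i in ids2], "hap2", True, False)
        pt = HaplotypePath("pt", [("t", PLUS)], "na", False, True)
        paths = [p1, p2, pt]
        if extra_big:
            paths.append(HaplotypePath("px", [("huge", PLUS)], "na"))
        matches = [
            HomologyMatch(a, b, 0, 1_800_000, 0, 1_800_000, 1_800_000, 0.99)
            for a, b in zip(ids1, ids2)
        ]
        return g, paths, matches

    def test_textbook_configuration_joins_stub(self):
        g, paths, matches = self._setup()
        joins = telomere_rescue(g, paths, matches)
        assert [(j.end1, j.end2) for j in joins] == [(("p2", SUFFIX), ("pt", PREFIX))]

    def test_second_large_path_in_component_blocks_rescue(self):
        g, paths, matches = self._setup(extra_big=True)
        assert telomere_rescue(g, paths, matches) == []

    def test_distant_stub_not_rescued(self):
        far = [f"f{i}" for i in range(4)]  # 4 x 150 kb = 600 kb intervening
        g, paths, matches = self._setup(stub_dist_nodes=far)
        assert telomere_rescue(g, paths, matches) == []
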