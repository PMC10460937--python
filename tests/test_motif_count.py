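import math

import pytest

from danai.contact_graph import ContactGraph, MacroClass
from danai.errors import UnsupportedPatternError
from danai.motif_count import (
    SemanticsConfig,
    closed_form_count,
    count_modes,
    count_pattern,
    macro_subgraph,
    pattern_automorphism_count,
)
from danai.notation import parse_danai

from conftest import make_random_graph


def graph(species, edges):
    return ContactGraph.from_edges(species, edges)


class TestMacroSubgraph:
    def test_filters_by_class(self):
        g = graph(["C182", "C182", "C180"], [(0, 1), (1, 2)])
        sub = macro_subgraph(g, MacroClass.ID_182_182)
        assert sub.edges == {(0, 1)}
        sub2 = macro_subgraph(g, MacroClass.ID_180_182)
        assert sub2.edges == {(1, 2)}

    def test_pure_system_has_empty_mixed_subgraph(self):
        g = graph(["C182"] * 4, [(0, 1), (2, 3)])
        assert macro_subgraph(g, MacroClass.ID_180_182).n_edges == 0

    def test_partition_property(self):
        g = make_random_graph(123)
        subs = [macro_subgraph(g, m) for m in MacroClass]
        union = set().union(*(s.edges for s in subs))
        assert union == g.edges
        assert sum(s.n_edges for s in subs) == g.n_edges

    def test_full_degree_retained(self):
        g = graph(["C182", "C182", "C180"], [(0, 1), (1, 2)])
        sub = macro_subgraph(g, MacroClass.ID_182_182)
        assert sub.full_degree == g.full_degree
        assert sub.full_degree[1] == 2


class TestCountPattern:
    def test_isolated_pair_upper_and_lower(self):
        g = graph(["C182", "C182"], [(0, 1)])
        assert count_pattern(g, parse_danai("[L2]C182:C182")) == 1
        assert count_pattern(g, parse_danai("[L2]c182:c182")) == 1

    def test_isolated_triangle_census(self):
        g = graph(["C182"] * 3, [(0, 1), (1, 2), (0, 2)])
        assert count_pattern(g, parse_danai("[R3]c182:c182:c182:c182")) == 1
        assert count_pattern(g, parse_danai("[L3]c182:c182:c182")) == 3
        assert count_pattern(g, parse_danai("[L2]c182:c182")) == 3
        assert count_pattern(g, parse_danai("[L2]C182:C182")) == 0

    def test_isolated_3star_census(self):
        g = graph(["C182"] * 4, [(0, 1), (0, 2), (0, 3)])
        assert count_pattern(g, parse_danai("[J4]C182:C182(:C182):C182")) == 1
        assert count_pattern(g, parse_danai("[L3]c182:c182:c182")) == 3
        assert count_pattern(g, parse_danai("[J5]c182:(c182:)c182(:c182):c182")) == 0

    def test_mixed_triangle_species_match(self):
        g = graph(["C182", "C180", "C182"], [(0, 1), (1, 2), (0, 2)])
        assert count_pattern(g, parse_danai("[R3]c182:c180:c182:c182")) == 1
        assert count_pattern(g, parse_danai("[R3]c182:c182:c182:c182")) == 0
        assert count_pattern(g, parse_danai("[R3]c180:c182:c180:c180")) == 0

    def test_exclusive_lowercase_needs_extra_contact(self):
        g = graph(["C182", "C182"], [(0, 1)])
        excl = SemanticsConfig(lowercase_mode="exclusive")
        assert count_pattern(g, parse_danai("[L2]c182:c182"), excl) == 0
        # a path of three: middle node has an extra contact for each end pair
        g3 = graph(["C182"] * 3, [(0, 1), (1, 2)])
        assert count_pattern(g3, parse_danai("[L2]c182:c182"), excl) == 0
        g4 = graph(["C182"] * 4, [(0, 1), (1, 2), (2, 3)])
        # middle edge: both endpoints have one extra contact each
        assert count_pattern(g4, parse_danai("[L2]c182:c182"), excl) == 1

    def test_case_scope_macro_vs_global(self):
        # C182-C182 pair where one endpoint also touches a C180
        g = graph(["C182", "C182", "C180"], [(0, 1), (1, 2)])
        up = parse_danai("[L2]C182:C182")
        assert count_pattern(g, up, SemanticsConfig(case_scope="global")) == 0
        assert count_pattern(g, up, SemanticsConfig(case_scope="macro")) == 1

    def test_unsupported_topology(self):
        g = graph(["C182", "C182"], [(0, 1)])
        with pytest.raises(UnsupportedPatternError):
            count_pattern(g, parse_danai("[L4]c182:c182:c182:c182"))
        with pytest.raises(UnsupportedPatternError):
            count_pattern(g, parse_danai("[R4]c182:c182:c182:c182:c182"))

    def test_node_relabelling_invariance(self):
        g = make_random_graph(5, n_min=15, n_max=25)
        perm = list(reversed(range(g.n_nodes)))
        edges2 = {(min(perm[u], perm[v]), max(perm[u], perm[v])) for u, v in g.edges}
        g2 = ContactGraph.from_edges(
            [g.species_of(perm[i]).code for i in range(g.n_nodes)], edges2
        )
        for stmt in ("[L2]c182:c180", "[L3]c182:c182:c182", "[J4]c180:c180(:c180):c180"):
            p = parse_danai(stmt)
            assert count_pattern(g, p) == count_pattern(g2, p)


class TestClosedForm:
    def test_k4(self):
        g = graph(["C182"] * 4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
        assert closed_form_count(g, parse_danai("[L3]c182:c182:c182")) == 12
        assert closed_form_count(g, parse_danai("[J4]c182:c182(:c182):c182")) == 4
        assert closed_form_count(g, parse_danai("[J5]c182:(c182:)c182(:c182):c182")) == 0

    def test_k14_star(self):
        g = graph(["C182"] * 5, [(0, i) for i in range(1, 5)])
        assert closed_form_count(g, parse_danai("[J5]c182:(c182:)c182(:c182):c182")) == 1
        assert closed_form_count(g, parse_danai("[J4]c182:c182(:c182):c182")) == 4
        assert closed_form_count(g, parse_danai("[L3]c182:c182:c182")) == 6

    def test_empty_graph(self):
        g = ContactGraph.from_edges(["C182", "C180"], [])
        for stmt in (
            "[L2]c182:c182",
            "[L3]c182:c182:c182",
            "[J4]c182:c182(:c182):c182",
            "[J5]c182:(c182:)c182(:c182):c182",
        ):
            assert closed_form_count(g, parse_danai(stmt)) == 0

    def test_equals_count_pattern_on_random_graphs(self):
        stmts = [
            "[L2]c182:c182",
            "[L3]c180:c180:c180",
            "[J4]c182:c182(:c182):c182",
            "[J5]c180:(c180:)c180(:c180):c180",
        ]
        for seed in range(6):
            g = make_random_graph(seed, n_min=20, n_max=40)
            for stmt in stmts:
                p = parse_danai(stmt)
                assert closed_form_count(g, p) == count_pattern(g, p)

    def test_rejects_uppercase_and_mixed(self):
        g = graph(["C182", "C182"], [(0, 1)])
        with pytest.raises(UnsupportedPatternError):
            closed_form_count(g, parse_danai("[L2]C182:C182"))
        with pytest.raises(UnsupportedPatternError):
            closed_form_count(g, parse_danai("[L3]c182:c180:c182"))
        with pytest.raises(UnsupportedPatternError):
            closed_form_count(g, parse_danai("[R3]c182:c182:c182:c182"))

    def test_closed_forms_match_degree_arithmetic(self):
        g = make_random_graph(77, n_min=30, n_max=50)
        sub = macro_subgraph(g, MacroClass.ID_182_182)
        degs = [len(nb) for v, nb in sub.adjacency.items()
                if g.species_of(v).code == "C182"]
        assert closed_form_count(g, parse_danai("[L2]c182:c182")) == sub.n_edges
        assert closed_form_count(g, parse_danai("[L3]c182:c182:c182")) == sum(
            math.comb(d, 2) for d in degs
        )


class TestCountModes:
    def test_empty_graph_all_zero(self, modes):
        g = ContactGraph.from_edges(["C182", "C180"], [])
        mc = count_modes(g, modes)
        assert set(mc.counts) == set(modes.statements)
        assert all(v == 0 for v in mc.counts.values())

    def test_uppercase_at_most_lowercase(self, modes):
        for seed in range(5):
            g = make_random_graph(seed + 100)
            mc = count_modes(g, modes).counts
            assert mc["[L2]C182:C182"] <= mc["[L2]c182:c182"]
            assert mc["[L2]C180:C180"] <= mc["[L2]c180:c180"]
            assert mc["[L2]C182:C180"] <= mc["[L2]c182:c180"]
            assert (
                mc["[J4]C182:C182(:C182):C182"] <= mc["[J4]c182:c182(:c182):c182"]
            )

    def test_l3_at_least_3_r3(self, modes):
        for seed in range(5):
            g = make_random_graph(seed + 200)
            mc = count_modes(g, modes).counts
            assert mc["[L3]c182:c182:c182"] >= 3 * mc["[R3]c182:c182:c182:c182"]
            assert mc["[L3]c180:c180:c180"] >= 3 * mc["[R3]c180:c180:c180:c180"]

    def test_l2_monotone_in_edges(self, modes):
        g = make_random_graph(300)
        edges = sorted(g.edges)
        species = [g.species_of(i).code for i in range(g.n_nodes)]
        g_small = ContactGraph.from_edges(species, edges[: len(edges) // 2])
        mc_small = count_modes(g_small, modes).counts
        mc_full = count_modes(g, modes).counts
        for stmt in ("[L2]c182:c182", "[L2]c180:c180", "[L2]c182:c180"):
            assert mc_small[stmt] <= mc_full[stmt]


class TestAutomorphisms:
    @pytest.mark.parametrize(
        "stmt,expected",
        [
            ("[L2]c182:c182", 2),
            ("[L2]c182:c180", 1),
            ("[L2]C182:c182", 1),
            ("[L3]c182:c182:c182", 2),
            ("[L3]c182:c180:c182", 2),
            ("[L3]c180:c182:c180", 2),
            ("[R3]c182:c182:c182:c182", 6),
            ("[R3]c182:c180:c182:c182", 2),
            ("[J4]c182:c182(:c182):c182", 6),
            ("[J5]c182:(c182:)c182(:c182):c182", 24),
        ],
    )
    def test_counts(self, stmt, expected):
        assert pattern_automorphism_count(parse_danai(stmt)) == expected
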