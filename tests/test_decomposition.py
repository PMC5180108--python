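"""Truss decomposition: peeling vs. definitional fixpoint, truss extraction.

The peeling path is validated by exact agreement with the naive
fixpoint oracle, and the defining properties of the decomposition —
nesting of the E_k link sets, disjointness of maximal trusses,
within-subgraph support, maximality, strong connectivity of cycle
trusses — are asserted on fixtures and randomized trials.
"""

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ditruss as dt
from conftest import random_small_graph


class TestTrussNumbersFixtures:
    @pytest.mark.parametrize("motif", dt.MOTIFS)
    def test_triangle_free_square_is_level_zero(self, motif):
        dec = dt.truss_numbers(dt.directed_cycle(4), motif)
        assert set(dec.truss_number.values()) == {0}
        assert dec.k_max == 0

    @pytest.mark.parametrize("n", range(3, 9))
    def test_complete_bidirectional_law(self, n):
        # Complete bidirectional graph on n nodes is simultaneously a
        # cycle (n-2)-truss and a flow 3(n-2)-truss.
        g = dt.complete_bidirectional(n)
        assert set(dt.truss_numbers(g, "cycle").truss_number.values()) == {n - 2}
        assert set(dt.truss_numbers(g, "flow").truss_number.values()) == {3 * (n - 2)}

    def test_transitive_tournament(self):
        g = dt.transitive_tournament(4)
        assert set(dt.truss_numbers(g, "flow").truss_number.values()) == {2}
        assert set(dt.truss_numbers(g, "cycle").truss_number.values()) == {0}

    def test_single_feedforward_triangle(self, feedforward):
        assert set(dt.truss_numbers(feedforward, "flow").truss_number.values()) == {1}

    def test_two_cycle_triangles_sharing_a_link(self):
        # The shared link has support 2 but cannot sustain level 2 once
        # its unshared partners (support 1) are peeled away.
        g, _ = dt.read_edge_list(iter(["1 2", "2 3", "3 1", "2 4", "4 1"]))
        dec = dt.truss_numbers(g, "cycle")
        assert set(dec.truss_number.values()) == {1}

    def test_empty_graph(self):
        dec = dt.truss_numbers(nx.DiGraph(), "cycle")
        assert dec.truss_number == {}
        assert dec.k_max == 0
        assert dt.max_truss_number(dec) == 0

    def test_max_truss_number_cases(self, three_cycle):
        assert dt.max_truss_number(dt.truss_numbers(dt.complete_bidirectional(4), "flow")) == 6
        assert dt.max_truss_number(dt.truss_numbers(three_cycle, "cycle")) == 1
        assert dt.max_truss_number(dt.truss_numbers(three_cycle, "flow")) == 0


class TestOracleEquivalence:
    @pytest.mark.parametrize("motif", dt.MOTIFS)
    @pytest.mark.parametrize("seed", range(25))
    def test_peeling_equals_fixpoint_on_random_graphs(self, motif, seed):
        g = random_small_graph(seed)
        assert (
            dt.truss_numbers(g, motif).truss_number
            == dt.naive_truss_numbers(g, motif).truss_number
        )

    @pytest.mark.parametrize("motif", dt.MOTIFS)
    def test_peeling_equals_fixpoint_on_denser_graph(self, motif):
        g = dt.er_directed(20, 0.25, seed=99)
        assert (
            dt.truss_numbers(g, motif).truss_number
            == dt.naive_truss_numbers(g, motif).truss_number
        )


class TestDecompositionProperties:
    @pytest.mark.parametrize("motif", dt.MOTIFS)
    @pytest.mark.parametrize("seed", range(8))
    def test_nesting_and_fixpoint(self, motif, seed):
        g = dt.er_directed(18, 0.25, seed=seed)
        dec = dt.truss_numbers(g, motif)
        support_fn = dt.cycle_support if motif == "cycle" else dt.flow_support
        assert dec.links_at_least(0) == set(g.edges())
        for k in range(1, dec.k_max + 2):
            ek, prev = dec.links_at_least(k), dec.links_at_least(k - 1)
            assert ek <= prev
            sub = nx.DiGraph()
            sub.add_edges_from(ek)
            for u, v in ek:
                assert support_fn(sub, u, v) >= k
        assert dec.links_at_least(dec.k_max)
        assert not dec.links_at_least(dec.k_max + 1)

    @pytest.mark.parametrize("motif", dt.MOTIFS)
    @pytest.mark.parametrize("seed", range(4))
    def test_top_level_maximality_under_readdition(self, motif, seed):
        # E_{k_max} is a fixpoint and maximal: putting any removed link
        # back breaks the support bound for some link.
        g = random_small_graph(seed, max_n=7)
        dec = dt.truss_numbers(g, motif)
        k = dec.k_max
        if k == 0:
            return
        ek = dec.links_at_least(k)
        support_fn = dt.cycle_support if motif == "cycle" else dt.flow_support
        for extra in set(g.edges()) - ek:
            sub = nx.DiGraph()
            sub.add_edges_from(ek | {extra})
            # the re-added link itself must fail the bound after re-peeling;
            # a single addition cannot rescue it to a level-k fixpoint
            aug = dt.naive_truss_numbers(sub, motif)
            assert aug.truss_number[extra] < k

    @pytest.mark.parametrize("seed", range(6))
    def test_truss_number_multiset_is_isomorphism_invariant(self, seed):
        g = random_small_graph(seed)
        h = nx.relabel_nodes(g, {n: f"z{n}" for n in g.nodes()})
        for motif in dt.MOTIFS:
            assert sorted(dt.truss_numbers(g, motif).truss_number.values()) == sorted(
                dt.truss_numbers(h, motif).truss_number.values()
            )


class TestExtractKTrusses:
    def test_complete_bidirectional_top_cycle_truss(self):
        g = dt.complete_bidirectional(5)
        trusses = dt.extract_k_trusses(g, "cycle", 3)
        assert len(trusses) == 1
        assert trusses[0].n_links == 20
        assert trusses[0].n_nodes == 5
        assert trusses[0].strongly_connected

    def test_disjoint_feedforward_triangles(self):
        g, _ = dt.read_edge_list(iter(["a b", "b c", "a c", "x y", "y z", "x z"]))
        trusses = dt.extract_k_trusses(g, "flow", 1)
        assert len(trusses) == 2
        assert sorted(t.n_links for t in trusses) == [3, 3]
        link_sets = [t.links for t in trusses]
        assert link_sets[0].isdisjoint(link_sets[1])

    def test_level_zero_is_weak_components(self):
        g = dt.er_directed(15, 0.1, seed=5)
        trusses = dt.extract_k_trusses(g, "cycle", 0)
        want = [set(c) for c in nx.weakly_connected_components(g) if len(c) > 1]
        got = [t.nodes for t in trusses]
        assert sorted(map(sorted, got)) == sorted(map(sorted, want))

    def test_empty_level(self, three_cycle):
        assert dt.extract_k_trusses(three_cycle, "cycle", 5) == []

    def test_negative_level_rejected(self, three_cycle):
        with pytest.raises(ValueError, match="non-negative"):
            dt.extract_k_trusses(three_cycle, "cycle", -1)

    @pytest.mark.parametrize("seed", range(8))
    def test_cycle_trusses_are_strongly_connected(self, seed):
        g = dt.er_directed(20, 0.2, seed=seed)
        dec = dt.truss_numbers(g, "cycle")
        for k in range(1, dec.k_max + 1):
            for t in dt.extract_k_trusses(g, "cycle", k, decomposition=dec):
                assert t.strongly_connected
                assert nx.is_strongly_connected(t.to_graph())

    @pytest.mark.parametrize("motif", dt.MOTIFS)
    @pytest.mark.parametrize("seed", range(4))
    def test_disjoint_links_and_nesting_across_levels(self, motif, seed):
        g = dt.er_directed(20, 0.2, seed=seed)
        dec = dt.truss_numbers(g, motif)
        prev_links = None
        for k in range(dec.k_max + 1):
            trusses = dt.extract_k_trusses(g, motif, k, decomposition=dec)
            seen = set()
            for t in trusses:
                assert seen.isdisjoint(t.links)
                seen |= t.links
            if prev_links is not None:
                assert seen <= prev_links
            prev_links = seen


@settings(deadline=None, max_examples=40, derandomize=True)
@given(seed=st.integers(0, 10_000), motif=st.sampled_from(dt.MOTIFS))
def test_peeling_equals_fixpoint_property(seed, motif):
    """Peeling and the definitional fixpoint agree on arbitrary small graphs."""
    g = random_small_graph(seed)
    assert (
        dt.truss_numbers(g, motif).truss_number
        == dt.naive_truss_numbers(g, motif).truss_number
    )
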