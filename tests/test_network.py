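"""Network structure, switchings, representation checks, decomposition."""

import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

from dcnet.enewick import parse_enewick, parse_newick_tree
from dcnet.network import (
    DecompositionStatus,
    NetworkError,
    PhyloNetwork,
    check_decomposition,
    maximal_subtrees,
    represents_all_softwired,
    represents_hardwired,
    represents_softwired,
    reticulation_number,
    switchings,
)
from dcnet.fixtures import random_tree

from conftest import cset, fs

# root->a, root->b, a->1, a->h, b->h, b->3, h->2 (one reticulation)
ONE_RETIC = PhyloNetwork(
    [("r", "a"), ("r", "b"), ("a", "l1"), ("a", "h"), ("b", "h"),
     ("b", "l3"), ("h", "l2")],
    {"l1": "1", "l2": "2", "l3": "3"},
)


class TestReticulationNumber:
    def test_tree_is_zero(self):
        t = parse_newick_tree("((1,2),3);")
        assert reticulation_number(t) == 0

    def test_one_reticulation_both_formulas(self):
        n = ONE_RETIC
        g = n.graph
        by_indeg = sum(g.in_degree(v) - 1 for v in g.nodes if g.in_degree(v) > 0)
        assert reticulation_number(n) == 1 == by_indeg
        assert g.number_of_edges() - g.number_of_nodes() + 1 == 1

    def test_third_parent_adds_one(self):
        edges = list(ONE_RETIC.graph.edges) + [("r", "h")]
        n = PhyloNetwork(edges, ONE_RETIC.labels)
        assert reticulation_number(n) == 2

    def test_multi_root_rejected(self):
        with pytest.raises(NetworkError):
            PhyloNetwork([("r1", "l1"), ("r2", "l2")], {"l1": "1", "l2": "2"})


class TestSwitchings:
    def test_tree_has_one(self):
        assert len(switchings(parse_newick_tree("((1,2),3);"))) == 1

    def test_one_reticulation_two(self):
        assert len(switchings(ONE_RETIC)) == 2

    def test_product_over_reticulations(self):
        n = parse_enewick("(((1)#H1,(2)#H2),(#H1,#H2,3));")
        assert len(switchings(n)) == 4


class TestSoftwiredHardwired:
    def test_tree_represents_its_clusters(self):
        t = parse_newick_tree("((1,2),3);")
        assert represents_softwired(t, fs(1, 2))
        assert not represents_softwired(t, fs(2, 3))

    @pytest.mark.parametrize("cluster,expected", [
        ({1, 2}, True),   # switch h to parent a
        ({2, 3}, True),   # switch h to parent b
        ({1, 3}, False),
    ])
    def test_one_reticulation_softwired(self, cluster, expected):
        assert represents_softwired(ONE_RETIC, fs(*cluster)) is expected

    def test_hardwired_differs_from_softwired(self):
        # descendants of a are {1,2}, of b are {2,3}: both present hardwired,
        # but {1,2,3} is only below the root
        assert represents_hardwired(ONE_RETIC, fs(1, 2))
        assert not represents_hardwired(ONE_RETIC, fs(1, 2, 3))

    def test_hardwired_tree_edge_below_reticulation(self):
        # (h, 2) is a tree edge: its head is the leaf
        assert represents_hardwired(ONE_RETIC, fs(2))

    def test_agreement_on_trees_exhaustive(self):
        r = random.Random(5)
        for _ in range(10):
            t = random_tree(r, r.randint(3, 7))
            taxa = sorted(t.leaf_labels())
            for k in range(1, len(taxa)):
                for combo in itertools.combinations(taxa, k):
                    c = frozenset(combo)
                    assert represents_softwired(t, c) == represents_hardwired(t, c)


class TestRepresentsAll:
    def test_tree_total_mapping(self):
        t = parse_newick_tree("((1,2),(3,4));")
        eps = represents_all_softwired(t, cset({1, 2}, {3, 4}))
        assert eps is not None and len(eps) == 2

    def test_one_reticulation_pair(self):
        assert represents_all_softwired(ONE_RETIC, cset({1, 2}, {2, 3})) is not None

    def test_absent_names_unrepresented(self):
        t = parse_newick_tree("((1,2),3);")
        assert represents_all_softwired(t, cset({2, 3})) is None


class TestDecomposition:
    def test_tree_with_compatible_set(self):
        t = parse_newick_tree("((1,2),(3,4));")
        assert check_decomposition(t, cset({1, 2}, {3, 4})) is DecompositionStatus.HOLDS

    def test_one_reticulation_pair(self):
        assert check_decomposition(ONE_RETIC, cset({1, 2}, {2, 3})) is DecompositionStatus.HOLDS

    def test_bridge_component_and_cycle_component(self):
        from dcnet.construct import build_network

        cs = cset({1, 2}, {2, 3}, {4, 5}, universe={1, 2, 3, 4, 5})
        net = build_network(cs).network
        assert check_decomposition(net, cs) is DecompositionStatus.HOLDS

    def test_merged_witnesses_fail(self):
        # both clusters of a compatible set forced through one biconnected
        # component would fail; a tree keeps them on distinct bridges
        t = parse_newick_tree("(((1,2),3),4);")
        assert check_decomposition(t, cset({1, 2}, {1, 2, 3})) is DecompositionStatus.HOLDS


class TestMaximalSubtrees:
    def test_tree_root_only(self):
        t = parse_newick_tree("((1,2),3);")
        assert [s for _, s in maximal_subtrees(t)] == [fs(1, 2, 3)]

    def test_one_reticulation_leaves_only(self):
        assert [s for _, s in maximal_subtrees(ONE_RETIC)] == [fs(1), fs(2), fs(3)]

    def test_decollapsed_cherry_is_maximal(self):
        from dcnet.construct import build_network

        cs = cset({1, 2}, {1, 2, 3}, {3, 4})
        net = build_network(cs).network
        assert fs(1, 2) in {s for _, s in maximal_subtrees(net)}


@given(st.integers(0, 10_000))
@settings(deadline=None, max_examples=25)
def test_reticulation_identity_on_built_networks(seed):
    from dcnet.construct import build_network
    from dcnet.fixtures import mixed_fixture

    r = random.Random(seed)
    cs, _ = mixed_fixture(r, seed % 10)
    net = build_network(cs, max_r=8).network
    g = net.graph
    assert (sum(g.in_degree(v) - 1 for v in g.nodes if g.in_degree(v) > 0)
            == g.number_of_edges() - g.number_of_nodes() + 1)
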