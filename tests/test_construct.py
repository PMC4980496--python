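"""The divide-and-conquer pipeline: Hasse backbone, transfer, fallback
search, merge, and end-to-end construction."""

import random

import pytest

from dcnet.catalog import entries, lookup
from dcnet.clusters import ClusterError, ClusterSet, clusters_of_tree
from dcnet.construct import (
    UnsupportedComponentError,
    build_component,
    build_network,
    fallback_search,
    hasse_tree,
    merge,
    transfer_network,
)
from dcnet.enewick import parse_newick_tree
from dcnet.fixtures import random_tree
from dcnet.incompat import ComponentTopology as T
from dcnet.isomorphism import networks_isomorphic
from dcnet.network import (
    maximal_subtrees,
    represents_all_softwired,
    reticulation_number,
)
from dcnet.simplify import to_simplest

from conftest import cset, fs


class TestHasseTree:
    def test_nested_clusters(self):
        t = hasse_tree(cset({1, 2}, {1, 2, 3}, universe={1, 2, 3, 4}))
        assert clusters_of_tree(t).clusters == frozenset([fs(1, 2), fs(1, 2, 3)])

    def test_no_clusters_star(self):
        t = hasse_tree(ClusterSet(fs(1, 2)))
        assert t.leaf_labels() == fs(1, 2)
        assert t.graph.number_of_edges() == 2

    def test_roundtrip_random_tree(self, rng):
        tree = random_tree(rng, 8)
        cs = clusters_of_tree(tree)
        rebuilt = hasse_tree(ClusterSet(tree.leaf_labels(), cs.clusters))
        assert networks_isomorphic(tree, rebuilt)

    def test_incompatible_rejected(self):
        with pytest.raises(ClusterError):
            hasse_tree(cset({1, 2}, {2, 3}))


class TestTransfer:
    def test_pair_transfer_with_block(self):
        target = cset({1, 2, 3}, {3, 4})
        res = to_simplest(target)
        entry, g = lookup(res.collapsed)
        net = transfer_network(entry.network, g, res, target)
        assert net.leaf_labels() == target.universe
        assert represents_all_softwired(net, target) is not None
        assert fs(1, 2) in {s for _, s in maximal_subtrees(net)}

    def test_identity_bijection_no_blocks(self):
        e = entries()[0]
        res = to_simplest(e.clusters)
        entry, g = lookup(res.collapsed)
        net = transfer_network(entry.network, g, res, e.clusters)
        assert networks_isomorphic(net, e.network.copy_relabeled(g.as_dict()))

    def test_renamed_target(self):
        target = cset({"a", "b"}, {"b", "c"})
        res = to_simplest(target)
        entry, g = lookup(res.collapsed)
        net = transfer_network(entry.network, g, res, target)
        assert represents_all_softwired(net, target) is not None


class TestFallback:
    def test_pair_one_reticulation(self):
        cs = cset({1, 2}, {2, 3})
        net = fallback_search(cs, max_r=1)
        assert reticulation_number(net) == 1
        assert represents_all_softwired(net, cs) is not None

    def test_compatible_rejected(self):
        with pytest.raises(ClusterError):
            fallback_search(cset({1, 2}, {1, 2, 3}))

    def test_zero_budget_unsupported(self):
        with pytest.raises(UnsupportedComponentError):
            fallback_search(cset({1, 2}, {2, 3}), max_r=0)

    def test_matches_catalog_reticulations(self):
        # independent search agrees with the frozen fixture's count for the
        # one-reticulation entries
        for e in entries():
            if reticulation_number(e.network) == 1:
                net = fallback_search(e.clusters, max_r=2)
                assert reticulation_number(net) == 1


class TestMerge:
    def test_component_plus_cherry(self):
        comp = cset({1, 2}, {2, 3})
        sub = build_component(comp, max_r=2)
        net = merge([(comp, sub)], [fs(4, 5)], fs(1, 2, 3, 4, 5))
        full = cset({1, 2}, {2, 3}, {4, 5}, universe={1, 2, 3, 4, 5})
        assert represents_all_softwired(net, full) is not None

    def test_no_components_plain_tree(self):
        net = merge([], [fs(1, 2)], fs(1, 2, 3))
        assert reticulation_number(net) == 0


class TestBuildNetwork:
    def test_single_tree_identity(self):
        t = parse_newick_tree("((1,(2,5)),(3,4));")
        res = build_network([t])
        assert reticulation_number(res.network) == 0
        assert networks_isomorphic(res.network, t)

    def test_pair_set(self):
        res = build_network(cset({1, 2}, {2, 3}))
        assert reticulation_number(res.network) == 1
        assert res.witness is not None
        assert res.per_component[0].topology is T.PAIR
        assert res.per_component[0].method.startswith("catalog:")

    def test_worked_example_cherry(self):
        res = build_network(cset({1, 2}, {1, 2, 3}, {3, 4}))
        assert fs(1, 2) in {s for _, s in maximal_subtrees(res.network)}

    def test_reticulations_sum_over_components(self):
        cs = cset({1, 2}, {2, 3}, {4, 5}, {5, 6}, universe={1, 2, 3, 4, 5, 6})
        res = build_network(cs)
        total = sum(c.reticulations for c in res.top_components())
        assert reticulation_number(res.network) == total == 2

    def test_nested_components(self):
        # one incompatible pair entirely inside another component's block
        cs = cset({1, 2}, {2, 3}, {1, 2, 3, 4}, {4, 5})
        res = build_network(cs, max_r=4)
        assert res.witness is not None

    def test_isolated_taxa_under_root(self):
        cs = cset({1, 2}, {2, 3}, universe={1, 2, 3, 9})
        res = build_network(cs)
        root_children_labels = {
            res.network.labels.get(v) for v in res.network.graph.successors(res.network.root)
        }
        assert "9" in root_children_labels

    def test_trivial_clusters_accepted(self):
        cs = ClusterSet(fs(1, 2, 3), frozenset([fs(1, 2), fs(2, 3), fs(1)]))
        res = build_network(cs)
        assert res.witness is not None

    def test_empty_input_rejected(self):
        with pytest.raises(ClusterError):
            build_network([])

    def test_spanning_cluster_via_root_edge(self):
        cs = cset({1, 2}, {2, 3}, {1, 2, 3}, universe={1, 2, 3, 4})
        res = build_network(cs)
        assert res.witness is not None

    def test_expanded_catalog_uses_catalog_path(self, rng):
        from dcnet.fixtures import expanded_catalog_clusters

        e = entries()[5]
        cs = expanded_catalog_clusters(rng, e.clusters, (1, 2))
        res = build_network(ClusterSet(cs.union, cs.clusters), max_r=6)
        methods = [c.method for c in res.per_component]
        assert any(m.startswith("catalog:") for m in methods)
        assert res.witness is not None
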