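"""Cluster-set isomorphism, canonical keys, network isomorphism."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from dcnet.catalog import entries
from dcnet.clusters import ClusterSet
from dcnet.enewick import parse_enewick, parse_newick_tree
from dcnet.fixtures import expanded_catalog_clusters, random_clusters
from dcnet.isomorphism import (
    SizeError,
    canonical_form,
    canonical_key,
    clustersets_isomorphic,
    networks_isomorphic,
)
from dcnet.simplify import to_simplest

from conftest import cset, union_form

C0 = [{1, 2}, {2, 3}]
C5 = [{1, 2}, {2, 3}, {1, 3}]


class TestClusterSetIsomorphism:
    def test_collapse_then_match(self):
        g = clustersets_isomorphic(cset({1, 2, 3}, {3, 4}), cset(*C0))
        assert g is not None
        # the composite {1,2} block plays taxon 1's role
        assert g.as_dict() == {"1+2": "1", "3": "2", "4": "3"}

    def test_renaming_is_isomorphic(self):
        a = cset({1, 2}, {2, 3}, {3, 4})
        b = cset({"a", "b"}, {"b", "c"}, {"c", "d"})
        assert clustersets_isomorphic(a, b) is not None

    def test_pair_vs_triangle_absent(self):
        assert clustersets_isomorphic(cset(*C0), cset(*C5)) is None

    def test_weak_vs_strong_interpretation(self):
        # two printed simplest sets with identical co-membership graphs
        # (K4 minus one edge) but different cluster-size multisets: the
        # pairwise reading accepts, the family reading refuses
        a = cset({1, 3}, {1, 2, 4}, {1, 2, 3})
        b = cset({1, 2, 4}, {1, 3}, {2, 3})
        assert clustersets_isomorphic(a, b, strong=True) is None
        assert clustersets_isomorphic(a, b, strong=False) is not None

    def test_equivalence_relation_on_random_triples(self):
        r = random.Random(42)
        sets = []
        for _ in range(6):
            e = entries()[r.randrange(len(entries()))]
            sets.append(union_form(expanded_catalog_clusters(r, e.clusters, (1, 2))))
        for a in sets:
            assert clustersets_isomorphic(a, a) is not None  # reflexive
        for a, b in zip(sets, sets[1:]):
            ab = clustersets_isomorphic(a, b)
            ba = clustersets_isomorphic(b, a)
            assert (ab is None) == (ba is None)  # symmetric
        for a, b, c in zip(sets, sets[1:], sets[2:]):
            ab = clustersets_isomorphic(a, b)
            bc = clustersets_isomorphic(b, c)
            if ab is not None and bc is not None:  # transitive
                assert clustersets_isomorphic(a, c) is not None


class TestCanonicalKey:
    def test_renamed_sets_share_keys(self):
        k1 = canonical_key(cset(*C0))
        k2 = canonical_key(cset({"a", "b"}, {"b", "c"}))
        assert k1 == k2

    def test_path_vs_triangle_keys_differ(self):
        assert canonical_key(cset({1, 2}, {2, 3}, {3, 4})) != canonical_key(cset(*C5))

    def test_key_matches_isomorphism_on_random_pairs(self):
        r = random.Random(7)
        for _ in range(25):
            a = union_form(random_clusters(r, r.randint(3, 6), r.randint(2, 4)))
            b = union_form(random_clusters(r, r.randint(3, 6), r.randint(2, 4)))
            sa, sb = to_simplest(a).collapsed, to_simplest(b).collapsed
            iso = clustersets_isomorphic(a, b) is not None
            keys_equal = canonical_form(sa)[0] == canonical_form(sb)[0]
            assert iso == keys_equal

    def test_size_bound(self):
        big = cset(*[{0, i} for i in range(1, 12)])
        with pytest.raises(SizeError):
            canonical_key(big)

    def test_catalog_keys_stable(self):
        # frozen spot-check: the pair entry's canonical encoding
        assert entries()[0].key.encoding == "n=3;0,2;1,2"


class TestNetworkIsomorphism:
    def test_node_renamed_copy(self):
        n = parse_enewick("((1,(2)#H1),(#H1,3));")
        m = parse_enewick("((#H7,3),((2)#H7,1));")
        assert networks_isomorphic(n, m)

    def test_different_trees(self):
        assert not networks_isomorphic(
            parse_newick_tree("((1,2),3);"), parse_newick_tree("(1,(2,3));")
        )

    def test_different_reticulation_placement(self):
        a = parse_enewick("((1,(2)#H1),(#H1,3));")
        b = parse_enewick("(((1)#H1,2),(#H1,3));")  # hybrid under taxon 1
        assert not networks_isomorphic(a, b)


@given(st.integers(0, 10_000))
@settings(deadline=None, max_examples=25)
def test_inverse_collapse_is_isomorphic(seed):
    """Expanding taxa of a simplest set into disjoint blocks yields a set
    isomorphic to the original (the transfer lemma's precondition)."""
    r = random.Random(seed)
    e = entries()[seed % len(entries())]
    expanded = expanded_catalog_clusters(r, e.clusters, (1, 3))
    assert clustersets_isomorphic(expanded, e.clusters) is not None
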