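"""Restriction, ST-sets, Collapse, and the simplest form."""

import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

from dcnet.clusters import ClusterError, are_compatible
from dcnet.simplify import (
    collapse_once,
    is_simplest,
    is_st_set,
    maximal_st_sets,
    restrict,
    subtree_for_block,
    to_simplest,
)
from dcnet.clusters import clusters_of_tree
from dcnet.fixtures import random_clusters

from conftest import cset, fs, union_form


class TestRestrict:
    def test_merges_and_drops(self):
        cs = cset({1, 2}, {1, 2, 3}, {3, 4})
        assert restrict(cs, fs(1, 2)).clusters == frozenset([fs(1, 2)])

    def test_full_universe_identity_up_to_improper(self):
        cs = cset({1, 2}, {1, 2, 3}, universe={1, 2, 3, 4})
        assert restrict(cs, cs.universe).clusters == cs.clusters

    def test_single_taxon(self):
        cs = cset({1, 2}, {2, 3})
        assert restrict(cs, fs(3)).clusters == frozenset([fs(3)])

    def test_outside_universe_rejected(self):
        with pytest.raises(ClusterError):
            restrict(cset({1, 2}, {2, 3}), fs(9))


class TestSTSets:
    def test_example_st_set(self):
        cs = cset({1, 2}, {1, 2, 3}, {3, 4})
        assert is_st_set(fs(1, 2), cs)

    def test_incompatible_candidate(self):
        assert not is_st_set(fs(2, 3), cset({1, 2}, {2, 3}))

    def test_singletons_are_not_st_sets(self):
        assert not is_st_set(fs(1), cset({1, 2}, {1, 2, 3}, {3, 4}))

    def test_whole_universe_excluded(self):
        assert not is_st_set(fs(1, 2, 3), cset({1, 2}, {1, 2, 3}, universe={1, 2, 3}))

    def test_maximal_worked_example(self):
        assert maximal_st_sets(cset({1, 2}, {1, 2, 3}, {3, 4})) == [fs(1, 2)]

    def test_simplest_set_has_none(self):
        assert maximal_st_sets(cset({1, 2}, {2, 3})) == []

    def test_disjoint_compatible_clusters(self):
        assert maximal_st_sets(cset({1, 2}, {3, 4})) == [fs(1, 2), fs(3, 4)]


class TestCollapse:
    def test_worked_example_single_round(self):
        res = collapse_once(cset({1, 2}, {1, 2, 3}, {3, 4}))
        s = next(t for t, b in res.block_map.items() if len(b) > 1)
        assert res.block_map[s] == fs(1, 2)
        assert res.collapsed.clusters == frozenset([fs(3, 4), frozenset([s, "3"])])
        assert res.dropped == frozenset([fs(1, 2)])

    def test_compatible_set_collapses_away(self):
        res = to_simplest(cset({1, 2}, {1, 2, 3}))
        assert not res.collapsed.clusters

    def test_simplest_input_unchanged(self):
        cs = cset({1, 2}, {2, 3})
        res = collapse_once(cs)
        assert res.collapsed == cs
        assert all(len(b) == 1 for b in res.block_map.values())

    def test_printed_simplest_set_unchanged(self):
        c12 = cset({1, 2, 3, 5}, {1, 2, 4, 6}, {1, 3, 4, 7})
        assert to_simplest(c12).collapsed == c12

    def test_nested_cluster_collapses(self):
        res = to_simplest(cset({1, 2, 3}, {3, 4}))
        assert res.composite_blocks() == [fs(1, 2)]
        assert len(res.collapsed.clusters) == 2

    @pytest.mark.parametrize("clusters", [
        [{1, 2}, {2, 3}],
        [{1, 2}, {1, 2, 3}, {3, 4}],
        [{1, 2, 3}, {3, 4, 5}, {5, 6}],
    ])
    def test_is_simplest_fixpoint(self, clusters):
        res = to_simplest(cset(*clusters))
        assert is_simplest(res.collapsed)
        again = to_simplest(res.collapsed)
        assert again.collapsed == res.collapsed

    def test_single_cluster_is_not_simplest(self):
        # the cluster itself is an ST-set
        assert not is_simplest(cset({1, 2}, universe={1, 2, 3}))


class TestSubtreeForBlock:
    def test_cherry(self):
        t = subtree_for_block(fs(1, 2), cset({1, 2}, {1, 2, 3}, {3, 4}))
        assert t.leaf_labels() == fs(1, 2)
        assert clusters_of_tree(t).clusters == frozenset()

    def test_nested_cluster_inside_block(self):
        cs = cset({1, 2}, {4, 5}, {1, 2, 3, 6}, universe={1, 2, 3, 4, 5, 6})
        t = subtree_for_block(fs(1, 2, 3), cs)
        assert clusters_of_tree(t).clusters == frozenset([fs(1, 2)])

    def test_not_an_st_set_rejected(self):
        with pytest.raises(ClusterError):
            subtree_for_block(fs(2, 3), cset({1, 2}, {2, 3}))


def _naive_st_sets(cs):
    """Independent brute force straight from the definition."""
    out = []
    taxa = sorted(cs.universe)
    for k in range(2, len(taxa)):
        for combo in itertools.combinations(taxa, k):
            s = frozenset(combo)
            if any(not are_compatible(s, c) for c in cs.clusters):
                continue
            inside = [c & s for c in cs.clusters]
            inside = [c for c in inside if c and c != s]
            if all(are_compatible(a, b) for a, b in itertools.combinations(inside, 2)):
                out.append(s)
    return out


@given(st.integers(0, 10_000))
@settings(deadline=None, max_examples=40)
def test_maximal_st_sets_match_naive_enumeration(seed):
    r = random.Random(seed)
    cs = union_form(random_clusters(r, r.randint(4, 8), r.randint(2, 5)))
    naive = _naive_st_sets(cs)
    expected = sorted(
        (s for s in naive if not any(s < t for t in naive)),
        key=lambda s: (len(s), tuple(sorted(s))),
    )
    assert maximal_st_sets(cs) == expected


@given(st.integers(0, 10_000))
@settings(deadline=None, max_examples=30)
def test_to_simplest_sound_and_roundtrips(seed):
    """The fixpoint has no ST-set, and expanding blocks plus dropped clusters
    recovers the original nontrivial clusters."""
    r = random.Random(seed)
    cs = union_form(random_clusters(r, r.randint(4, 8), r.randint(2, 5)))
    res = to_simplest(cs)
    assert is_simplest(res.collapsed)
    assert res.expanded_nontrivial() == frozenset(
        c for c in cs.clusters if len(c) > 1
    )
    # blocks partition the original universe
    blocks = list(res.block_map.values())
    assert frozenset().union(*blocks) == cs.universe
    assert sum(len(b) for b in blocks) == len(cs.universe)


@given(st.integers(0, 10_000))
@settings(deadline=None, max_examples=30)
def test_pairmerge_matches_bruteforce_maximal_st_sets(seed):
    """The scalable ST-pair-merging computation agrees with exhaustive
    subset enumeration wherever the latter is feasible."""
    from dcnet.simplify import _maximal_st_sets_bruteforce, _maximal_st_sets_pairmerge

    r = random.Random(seed)
    cs = union_form(random_clusters(r, r.randint(4, 9), r.randint(2, 6)))
    assert _maximal_st_sets_pairmerge(cs) == _maximal_st_sets_bruteforce(cs)
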