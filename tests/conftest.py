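import random

import pytest

from dcnet.clusters import ClusterSet
from dcnet.simplify import maximal_st_sets


def cset(*clusters, universe=None):
    """Shorthand: cset({1,2},{2,3}) with int or str members."""
    cl = [frozenset(str(t) for t in c) for c in clusters]
    uni = frozenset(str(t) for t in universe) if universe is not None else None
    return ClusterSet.from_clusters(cl, uni)


def fs(*members):
    return frozenset(str(t) for t in members)


def input_maximal_st_sets(nt: ClusterSet):
    """Maximal ST-sets of a nontrivial cluster set under the union-universe
    convention; spanning clusters (equal to the union) are ST-neutral —
    compatible with everything, improper in every restriction — and are
    peeled off until the convention applies."""
    clusters = set(nt.clusters)
    while clusters:
        uni = frozenset().union(*clusters)
        spans = [c for c in clusters if c == uni]
        if not spans:
            return maximal_st_sets(ClusterSet(uni, frozenset(clusters)))
        clusters -= set(spans)
    return []


def union_form(cs: ClusterSet) -> ClusterSet:
    """Union-universe form of a nontrivial cluster set, peeling spanning
    clusters (equal to the union) which the convention cannot represent."""
    clusters = {c for c in cs.clusters if len(c) > 1}
    while clusters:
        uni = frozenset().union(*clusters)
        spans = [c for c in clusters if c == uni]
        if not spans:
            return ClusterSet(uni, frozenset(clusters))
        clusters -= set(spans)
    raise ValueError("no nontrivial non-spanning clusters")


@pytest.fixture
def rng():
    return random.Random(987654321)
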