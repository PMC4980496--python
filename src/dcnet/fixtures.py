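"""Seeded synthetic inputs: random trees, expanded catalog entries, and
random cluster sets.

``expanded-catalog`` fixtures operationalize the network-transfer lemma:
each taxon of a catalog entry is replaced by a disjoint block of fresh
taxa (the inverse of collapsing), so collapsing the fixture back to its
simplest form must recover the originating entry — the end-to-end test of
the isomorphism machinery.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass

from .clusters import ClusterSet, are_compatible
from .network import RootedTree


@dataclass(frozen=True)
class FixtureSpec:
    kind: str  # random-trees | expanded-catalog | random-clusters
    n_taxa: int = 8
    n_items: int = 4
    seed: int = 0
    block_size_range: tuple = (1, 3)


def random_tree(rng: random.Random, n_taxa: int, prefix: str = "t") -> RootedTree:
    """A uniform-ish random rooted binary tree via recursive random splits."""
    labels = [f"{prefix}{i + 1}" for i in range(n_taxa)]
    counter = itertools.count()

    def grow(leaves):
        if len(leaves) == 1:
            return ("leaf", leaves[0]), [], {("leaf", leaves[0]): leaves[0]}
        k = rng.randint(1, len(leaves) - 1)
        shuffled = list(leaves)
        rng.shuffle(shuffled)
        left, right = sorted(shuffled[:k]), sorted(shuffled[k:])
        node = ("int", next(counter))
        lr, le, ll = grow(left)
        rr, re, rl = grow(right)
        edges = le + re + [(node, lr), (node, rr)]
        return node, edges, {**ll, **rl}

    root, edges, leaf_labels = grow(labels)
    if not edges:
        return RootedTree([], leaf_labels)
    return RootedTree(edges, leaf_labels)


def expanded_catalog_clusters(rng: random.Random, entry_clusters: ClusterSet,
                              block_size_range: tuple = (1, 3)) -> ClusterSet:
    """Replace every taxon of a (simplest) cluster set by a disjoint block of
    fresh taxa; collapsing the result recovers a set isomorphic to the input."""
    lo, hi = block_size_range
    counter = itertools.count(1)
    blocks = {}
    for t in sorted(entry_clusters.universe):
        size = rng.randint(lo, hi)
        blocks[t] = frozenset(f"x{next(counter)}" for _ in range(size))
    clusters = [
        frozenset().union(*(blocks[t] for t in c))
        for c in entry_clusters.sorted_clusters()
    ]
    return ClusterSet.from_clusters(clusters)


def random_clusters(rng: random.Random, n_taxa: int, n_items: int,
                    max_tries: int = 200) -> ClusterSet:
    """Random nontrivial proper clusters over taxa 1..n_taxa, rejected until
    at least one incompatible pair is present; universe is the union."""
    taxa = [str(i + 1) for i in range(n_taxa)]
    for _ in range(max_tries):
        out = set()
        for _ in range(n_items):
            size = rng.randint(2, max(2, n_taxa - 1))
            out.add(frozenset(rng.sample(taxa, size)))
        cl = sorted(out, key=lambda c: (len(c), tuple(sorted(c))))
        has_conflict = any(
            not are_compatible(a, b)
            for i, a in enumerate(cl) for b in cl[i + 1:]
        )
        if has_conflict:
            # sizes are capped below n_taxa, so clusters are proper subsets
            # of the full taxon set (taxa outside every cluster may remain)
            return ClusterSet(frozenset(taxa), frozenset(cl))
    raise RuntimeError("could not generate an incompatible cluster set")


def mixed_fixture(rng: random.Random, index: int):
    """One fixture of the soundness mix: ClusterSet plus a kind tag.

    Roughly 40% random cluster sets, 30% expanded catalog entries, 30%
    random trees (as their compatible cluster sets), capped at 8 taxa and 6
    clusters.
    """
    from .catalog import entries
    from .clusters import clusters_of_tree

    roll = index % 10
    if roll < 4:
        cs = random_clusters(rng, rng.randint(4, 8), rng.randint(2, 6))
        return cs, "random-clusters"
    if roll < 7:
        entry = entries()[rng.randrange(len(entries()))]
        hi = 2 if len(entry.clusters.universe) > 4 else 3
        cs = expanded_catalog_clusters(rng, entry.clusters, (1, hi))
        return cs, f"expanded:{entry.name}"
    t = random_tree(rng, rng.randint(3, 8))
    cs = clusters_of_tree(t)
    return cs, "tree"
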