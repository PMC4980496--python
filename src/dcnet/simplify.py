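"""Restriction, ST-sets, and Collapse to the simplest form.

An *ST-set* (strict tree set) of a cluster set C is a taxon subset S with
|S| > 1 that is compatible with every cluster and whose restriction C|_S is
itself compatible — i.e. S behaves like the leaf set of a clean subtree.
Collapsing every maximal ST-set into a single composite taxon and iterating
to a fixpoint yields the *simplest* form, the canonical object the catalog
is keyed on.  The whole universe is never an ST-set candidate (collapsing
it would destroy the instance).

Isolated taxa (in no cluster) and spanning clusters (equal to the union)
are tolerated here because restriction naturally produces them, but they
can make maximal ST-sets overlap, which raises :class:`STSetError`;
isomorphism and catalog operations enforce the stricter union-universe
convention.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .clusters import (
    ClusterError,
    ClusterSet,
    are_compatible,
    cluster_sort_key,
    is_compatible_set,
)
from .network import RootedTree, hasse_tree_raw

ST_UNIVERSE_LIMIT = 16  # exhaustive subset enumeration bound


class STSetError(RuntimeError):
    """An internal assumption about ST-sets was violated (with witnesses)."""


@dataclass
class CollapseResult:
    """Outcome of collapsing maximal ST-sets.

    ``block_map`` sends every taxon of ``collapsed.universe`` to the subset
    of *original* taxa it stands for (identity blocks for untouched taxa);
    ``dropped`` holds original clusters that became trivial, improper or
    duplicate while collapsing.  ``rounds`` counts collapse passes.
    """

    collapsed: ClusterSet
    block_map: dict = field(default_factory=dict)
    dropped: frozenset = frozenset()
    rounds: int = 0

    def composite_blocks(self) -> list:
        """Blocks of size > 1, sorted; these are the collapsed ST-sets."""
        return sorted((b for b in self.block_map.values() if len(b) > 1),
                      key=cluster_sort_key)

    def expand_cluster(self, c) -> frozenset:
        return frozenset().union(*(self.block_map[t] for t in c))

    def expanded_nontrivial(self) -> frozenset:
        """Nontrivial original clusters recovered from collapsed + dropped."""
        out = {self.expand_cluster(c) for c in self.collapsed.clusters}
        out |= set(self.dropped)
        return frozenset(c for c in out if len(c) > 1)


def restrict(cs: ClusterSet, s) -> ClusterSet:
    """The restriction C|_S: each cluster intersected with S.

    Empty intersections vanish and duplicates merge; an intersection equal
    to S itself is kept (it is compatible with everything in the
    restriction, so downstream compatibility tests are unaffected).
    """
    s = frozenset(s)
    if not s <= cs.universe:
        raise ClusterError(f"{sorted(s - cs.universe)} not in the universe")
    if not s:
        raise ClusterError("cannot restrict to the empty set")
    kept = {c & s for c in cs.clusters}
    return ClusterSet(s, frozenset(c for c in kept if c))


def is_st_set(s, cs: ClusterSet) -> bool:
    """|S| > 1, S compatible with every cluster, restriction compatible.

    S equal to the whole universe is excluded.
    """
    s = frozenset(s)
    if not s <= cs.universe:
        raise ClusterError(f"{sorted(s - cs.universe)} not in the universe")
    if len(s) <= 1 or s == cs.universe:
        return False
    if any(not are_compatible(s, c) for c in cs.clusters):
        return False
    return is_compatible_set(restrict(cs, s))


def _all_st_sets(cs: ClusterSet):
    n = len(cs.universe)
    if n > ST_UNIVERSE_LIMIT:
        raise ClusterError(
            f"exhaustive ST-set enumeration supports at most {ST_UNIVERSE_LIMIT} taxa, got {n}"
        )
    taxa = sorted(cs.universe)
    for size in range(2, n):  # size == n is the whole universe, excluded
        for combo in itertools.combinations(taxa, size):
            s = frozenset(combo)
            if is_st_set(s, cs):
                yield s


def _has_st_pair(clusters, taxa) -> bool:
    """Is some two-taxon subset an ST-set?

    A pair {x, y} (not the whole universe) is an ST-set iff no nontrivial
    cluster contains exactly one of x, y; its restriction is automatically
    compatible.  Every ST-set S contains such a pair: the restriction C|_S
    is compatible, and two leaves under the lowest node of its containment
    tree can be separated by no cluster.  So "no ST-pair" is equivalent to
    "simplest".
    """
    if len(taxa) <= 2:
        return False
    nontrivial = [c for c in clusters if len(c) > 1]
    for x, y in itertools.combinations(sorted(taxa), 2):
        if all((x in c) == (y in c) for c in nontrivial):
            return True
    return False


def _maximal_st_sets_bruteforce(cs: ClusterSet) -> list:
    sts = list(_all_st_sets(cs))
    maximal = [s for s in sts if not any(s < t for t in sts)]
    maximal.sort(key=cluster_sort_key)
    for a, b in itertools.combinations(maximal, 2):
        if a & b:
            raise STSetError(
                f"maximal ST-sets overlap: {sorted(a)} and {sorted(b)}"
            )
    return maximal


def _maximal_st_sets_pairmerge(cs: ClusterSet) -> list:
    """Maximal ST-sets by iterated merging of ST-pairs.

    Each merge collapses an ST-pair into one representative; the fixpoint's
    blocks of size > 1 are the maximal ST-sets.  Scales to large universes
    where subset enumeration cannot.
    """
    block = {t: frozenset([t]) for t in cs.universe}
    clusters = {c for c in cs.clusters if len(c) > 1}
    changed = True
    while changed and len(block) > 2:
        changed = False
        for x, y in itertools.combinations(sorted(block), 2):
            if any((x in c) != (y in c) for c in clusters):
                continue
            z = min(x, y)
            dead = y if z == x else x
            block[z] = block[x] | block[y]
            del block[dead]
            clusters = {
                frozenset(t for t in c if t != dead) | ({z} if dead in c else frozenset())
                for c in clusters
            }
            clusters = {c for c in clusters if len(c) > 1}
            changed = True
            break
    return sorted((b for b in block.values() if len(b) > 1), key=cluster_sort_key)


def maximal_st_sets(cs: ClusterSet) -> list:
    """All ST-sets not properly contained in another ST-set, sorted.

    The collapse semantics assume maximal ST-sets are pairwise disjoint;
    on small universes this is checked by exhaustive enumeration and
    violated pairs are reported rather than silently resolved (universes
    with isolated taxa or spanning clusters can make maximal ST-sets
    overlap).  Larger universes use ST-pair merging, which constructs the
    disjoint partition directly.
    """
    if len(cs.universe) <= 11:
        return _maximal_st_sets_bruteforce(cs)
    return _maximal_st_sets_pairmerge(cs)


def is_simplest(cs: ClusterSet) -> bool:
    """True iff no ST-set exists (equivalently: no two-taxon ST-set)."""
    return not _has_st_pair(cs.clusters, cs.universe)


def _composite_name(block, taken) -> str:
    name = "+".join(sorted(block))
    while name in taken:
        name += "x"
    return name


def _collapse_pass(cs: ClusterSet, expansion: dict):
    """One simultaneous collapse of all maximal ST-sets.

    ``expansion`` maps current taxa to original taxon sets; composite names
    are derived from the sorted original blocks so multi-round names stay
    stable and diffable.
    """
    msts = maximal_st_sets(cs)
    if not msts:
        return None
    rep = {}
    new_expansion = {}
    taken = set(cs.universe)
    for s in msts:
        block = frozenset().union(*(expansion[t] for t in s))
        name = _composite_name(block, taken)
        taken.add(name)
        new_expansion[name] = block
        for t in s:
            rep[t] = name
    for t in cs.universe:
        if t not in rep:
            rep[t] = t
            new_expansion[t] = expansion[t]
    new_universe = frozenset(rep.values())
    kept = set()
    dropped = set()
    for c in sorted(cs.clusters, key=cluster_sort_key):
        image = frozenset(rep[t] for t in c)
        if len(image) == 1 or image == new_universe or image in kept:
            dropped.add(frozenset().union(*(expansion[t] for t in c)))
        else:
            kept.add(image)
    return ClusterSet(new_universe, frozenset(kept)), new_expansion, dropped


def collapse_once(cs: ClusterSet) -> CollapseResult:
    """A single simultaneous collapse of the maximal ST-sets (one pass)."""
    expansion = {t: frozenset([t]) for t in cs.universe}
    res = _collapse_pass(cs, expansion)
    if res is None:
        return CollapseResult(cs, expansion, frozenset(), 0)
    collapsed, new_expansion, dropped = res
    return CollapseResult(collapsed, new_expansion, frozenset(dropped), 1)


def to_simplest(cs: ClusterSet) -> CollapseResult:
    """Collapse repeatedly until no ST-set remains.

    A single pass is the textbook Collapse; nothing rules out a pass
    creating new ST-sets, so the fixpoint is iterated and the block map is
    composed across rounds (blocks always name original taxa).
    """
    expansion = {t: frozenset([t]) for t in cs.universe}
    dropped: set = set()
    current = cs
    rounds = 0
    while True:
        res = _collapse_pass(current, expansion)
        if res is None:
            break
        current, expansion, drop = res
        dropped |= drop
        rounds += 1
        if not current.clusters:
            break
    return CollapseResult(current, expansion, frozenset(dropped), rounds)


def subtree_for_block(s, cs: ClusterSet) -> RootedTree:
    """The subtree a maximal ST-set stands for: a rooted tree on S whose
    nontrivial clusters are exactly the clusters of ``cs`` strictly inside S."""
    s = frozenset(s)
    if not is_st_set(s, cs):
        raise ClusterError(f"{sorted(s)} is not an ST-set of {cs!r}")
    inner = [c for c in cs.clusters if c < s]
    return hasse_tree_raw(s, inner)
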