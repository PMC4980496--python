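"""Cluster algebra: taxa, clusters, compatibility, cluster extraction from trees.

A *cluster* is a nonempty proper subset of a taxon universe; it is *trivial*
if it is a singleton.  Two clusters are *compatible* when they are disjoint
or nested — exactly the condition under which both can be descendant sets of
edges of one rooted tree.  A :class:`ClusterSet` bundles a universe with a
set of distinct clusters and is the central input object of the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .network import RootedTree

logger = logging.getLogger(__name__)

Taxon = str
Cluster = frozenset  # frozenset[Taxon]

_FORBIDDEN = set(",()# \t\n;:'\"")


class ClusterError(ValueError):
    """Invalid cluster or cluster-set input."""


def validate_label(label: str) -> str:
    """Check a taxon label: non-empty, no commas/whitespace/parentheses/'#'."""
    if not isinstance(label, str) or not label:
        raise ClusterError(f"taxon label must be a non-empty string, got {label!r}")
    bad = set(label) & _FORBIDDEN
    if bad:
        raise ClusterError(f"taxon label {label!r} contains forbidden characters {sorted(bad)}")
    return label


def _as_cluster(members: Iterable[Taxon]) -> Cluster:
    c = frozenset(members)
    if not c:
        raise ClusterError("empty cluster")
    return c


@dataclass(frozen=True)
class ClusterSet:
    """A taxon universe together with a set of distinct nonempty clusters.

    Clusters are normally proper subsets of the universe, but restriction
    can produce a cluster equal to its (restricted) universe, so equality
    is tolerated by the container; the network builder represents such a
    spanning cluster by the edge into the subnetwork root.  The universe
    may also be a strict superset of the union of the clusters (isolated
    taxa are accepted by the top-level builder); isomorphism and catalog
    operations require the universe to equal the union, see
    :func:`union_universe`.
    """

    universe: frozenset
    clusters: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        universe = frozenset(self.universe)
        clusters = frozenset(_as_cluster(c) for c in self.clusters)
        for t in universe:
            validate_label(t)
        for c in clusters:
            if not c <= universe:
                raise ClusterError(f"cluster {sorted(c)} not within universe {sorted(universe)}")
        if not universe:
            raise ClusterError("empty taxon universe")
        object.__setattr__(self, "universe", universe)
        object.__setattr__(self, "clusters", clusters)

    @classmethod
    def from_clusters(cls, clusters: Iterable[Iterable[Taxon]], universe: Iterable[Taxon] | None = None) -> "ClusterSet":
        """Build a ClusterSet; universe defaults to the union of the clusters."""
        cl = [frozenset(c) for c in clusters]
        if universe is None:
            uni = frozenset().union(*cl) if cl else frozenset()
        else:
            uni = frozenset(universe)
        return cls(uni, frozenset(cl))

    # -- convenience ---------------------------------------------------

    @property
    def union(self) -> frozenset:
        return frozenset().union(*self.clusters) if self.clusters else frozenset()

    def nontrivial(self) -> "ClusterSet":
        """Drop trivial (singleton) clusters; universe unchanged."""
        return ClusterSet(self.universe, frozenset(c for c in self.clusters if len(c) > 1))

    def sorted_clusters(self) -> list:
        return sorted(self.clusters, key=cluster_sort_key)

    def __iter__(self):
        return iter(self.sorted_clusters())

    def __len__(self):
        return len(self.clusters)

    def __contains__(self, c) -> bool:
        return frozenset(c) in self.clusters

    def __repr__(self):  # compact, deterministic
        cl = ", ".join("{" + ",".join(sorted(c)) + "}" for c in self.sorted_clusters())
        return f"ClusterSet(universe={{{','.join(sorted(self.universe))}}}, clusters=[{cl}])"


def cluster_sort_key(c: Cluster) -> tuple:
    """Deterministic ordering of clusters: by size, then sorted labels."""
    return (len(c), tuple(sorted(c)))


def union_universe(cs: ClusterSet) -> ClusterSet:
    """Require universe == union of clusters, as canonical-form operations do.

    Raises :class:`ClusterError` if taxa outside every cluster are present —
    such taxa would create spurious isomorphism classes.
    """
    extra = cs.universe - cs.union
    if extra:
        raise ClusterError(
            f"taxa {sorted(extra)} occur in no cluster; this operation requires "
            "the universe to equal the union of the clusters"
        )
    return cs


# -- operations --------------------------------------------------------


def is_trivial(c: Cluster) -> bool:
    """A cluster is trivial iff it has exactly one member."""
    c = _as_cluster(c)
    return len(c) == 1


def are_compatible(c1: Cluster, c2: Cluster) -> bool:
    """Disjoint or nested. Symmetric."""
    c1, c2 = frozenset(c1), frozenset(c2)
    inter = c1 & c2
    return not inter or inter == c1 or inter == c2


def incompatible_taxa(c1: Cluster, c2: Cluster) -> Cluster:
    """The intersection of two *incompatible* clusters (their shared taxa)."""
    c1, c2 = frozenset(c1), frozenset(c2)
    if are_compatible(c1, c2):
        raise ClusterError(f"clusters {sorted(c1)} and {sorted(c2)} are compatible")
    return c1 & c2


def is_compatible_set(cs: ClusterSet) -> bool:
    """True iff every pair of clusters is compatible (tree-representable)."""
    cl = cs.sorted_clusters()
    for i, a in enumerate(cl):
        for b in cl[i + 1:]:
            if not are_compatible(a, b):
                return False
    return True


def clusters_of_tree(t: "RootedTree", include_trivial: bool = False) -> ClusterSet:
    """Clusters represented by a rooted tree.

    For each edge (u, v) the descendant leaf-label set of v is collected.
    The full leaf set (the root's cluster) is never included; singletons are
    included only with ``include_trivial``.  The universe is the tree's leaf
    label set.
    """
    universe = frozenset(t.leaf_labels())
    out = set()
    desc = t.descendant_labels()
    for v in t.graph.nodes:
        if v == t.root:
            continue
        c = desc[v]
        if c == universe:
            continue
        if len(c) == 1 and not include_trivial:
            continue
        out.add(frozenset(c))
    return ClusterSet(universe, frozenset(out))
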