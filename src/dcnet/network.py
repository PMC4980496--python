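"""Rooted phylogenetic networks: DAG container, reticulations, switchings,
softwired/hardwired representation checks and the decomposition property.

A rooted phylogenetic network is a rooted DAG whose leaves are bijectively
labelled by taxa.  A node with indegree >= 2 is *reticulate*; the
reticulation number is sum(indeg(v) - 1) over nodes with indeg(v) > 0,
which equals |E| - |V| + 1 for a connected rooted DAG.  A *switching* keeps
exactly one incoming edge per reticulate node; the result is a spanning
tree of the node set.  A network represents a cluster C in the *softwired*
sense if some switching contains a tree edge whose descendant leaf set
equals C, and in the *hardwired* sense if such an edge exists in the
unswitched network.
"""

from __future__ import annotations

import enum
import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .clusters import ClusterSet, cluster_sort_key, validate_label

logger = logging.getLogger(__name__)

SWITCHING_CAP = 65536  # refuse to enumerate more switchings than this
WITNESS_EDGE_CAP = 32  # alternative witness edges per cluster in decomposition search


class NetworkError(ValueError):
    """Invalid network structure."""


class ResourceError(RuntimeError):
    """A configured search/enumeration cap was exceeded."""


class PhyloNetwork:
    """A rooted phylogenetic network over a taxon set.

    Nodes are arbitrary hashable identifiers; leaf nodes carry taxon labels.
    The graph is validated on construction: acyclic, a single root of
    indegree 0, every leaf (outdegree 0) labelled, labels distinct, and no
    parallel edges (networkx DiGraph cannot hold them; duplicate edge input
    collapses silently, which we detect by edge count when requested).
    """

    def __init__(self, edges: Iterable[tuple], leaf_labels: Mapping):
        g = nx.DiGraph()
        edge_list = list(edges)
        g.add_edges_from(edge_list)
        if len(edge_list) != g.number_of_edges():
            logger.warning("parallel/duplicate edges collapsed on network construction")
        if g.number_of_nodes() == 0:
            if not leaf_labels or len(leaf_labels) != 1:
                raise NetworkError("empty network")
            # single node, no edges: the root is the only leaf
            g.add_node(next(iter(leaf_labels)))
        if not nx.is_directed_acyclic_graph(g):
            raise NetworkError("network contains a directed cycle")
        roots = [v for v in g.nodes if g.in_degree(v) == 0]
        if len(roots) != 1:
            raise NetworkError(f"network must have exactly one root, found {len(roots)}")
        if not nx.is_weakly_connected(g):
            raise NetworkError("network is not connected")
        self.graph = g
        self.root = roots[0]
        leaves = [v for v in g.nodes if g.out_degree(v) == 0]
        labels = dict(leaf_labels)
        missing = [v for v in leaves if v not in labels]
        if missing:
            raise NetworkError(f"unlabelled leaves: {missing}")
        extra = [v for v in labels if v not in leaves]
        if extra:
            raise NetworkError(f"labels on non-leaf nodes: {extra}")
        vals = list(labels.values())
        if len(set(vals)) != len(vals):
            raise NetworkError("duplicate leaf labels")
        for lab in vals:
            validate_label(lab)
        self.labels = labels
        self.node_of_label = {lab: v for v, lab in labels.items()}

    # -- basic queries -------------------------------------------------

    def leaf_labels(self) -> frozenset:
        return frozenset(self.labels.values())

    def is_reticulate(self, v) -> bool:
        return self.graph.in_degree(v) >= 2

    def reticulate_nodes(self) -> list:
        return sorted((v for v in self.graph.nodes if self.is_reticulate(v)), key=str)

    def is_tree_edge(self, u, v) -> bool:
        """An edge (u, v) is a tree edge iff its head v is a tree node."""
        return self.graph.in_degree(v) <= 1

    def descendant_labels(self) -> dict:
        """Map node -> frozenset of leaf labels reachable below it (full graph)."""
        out = {}
        for v in reversed(list(nx.topological_sort(self.graph))):
            acc = set()
            if self.graph.out_degree(v) == 0:
                acc.add(self.labels[v])
            for w in self.graph.successors(v):
                acc |= out[w]
            out[v] = frozenset(acc)
        return out

    def copy_relabeled(self, mapping: Mapping) -> "PhyloNetwork":
        """Copy with leaf labels sent through ``mapping`` (label -> label)."""
        new_labels = {v: mapping.get(lab, lab) for v, lab in self.labels.items()}
        return PhyloNetwork(self.graph.edges(), new_labels)

    def __repr__(self):
        return (f"<{type(self).__name__} leaves={sorted(self.labels.values())} "
                f"r={reticulation_number(self)}>")


class RootedTree(PhyloNetwork):
    """A rooted phylogenetic tree: every non-root node has exactly one parent."""

    def __init__(self, edges, leaf_labels):
        super().__init__(edges, leaf_labels)
        bad = [v for v in self.graph.nodes if self.graph.in_degree(v) > 1]
        if bad:
            raise NetworkError(f"tree has reticulate nodes: {bad}")


# -- reticulations and switchings --------------------------------------


def reticulation_number(n: PhyloNetwork) -> int:
    """sum(indeg - 1) over non-root nodes; asserted equal to |E| - |V| + 1."""
    g = n.graph
    by_indeg = sum(g.in_degree(v) - 1 for v in g.nodes if g.in_degree(v) > 0)
    by_count = g.number_of_edges() - g.number_of_nodes() + 1
    if by_indeg != by_count:
        raise NetworkError(
            f"reticulation identity violated: sum(indeg-1)={by_indeg}, |E|-|V|+1={by_count}"
        )
    return by_indeg


@dataclass(frozen=True)
class Switching:
    """One retained incoming edge per reticulate node."""

    choice: tuple  # tuple of (parent, retic) edges, sorted


def switchings(n: PhyloNetwork, cap: int = SWITCHING_CAP) -> list:
    """All switchings, as the Cartesian product of retained in-edges."""
    retics = n.reticulate_nodes()
    count = 1
    options = []
    for r in retics:
        ins = sorted(n.graph.in_edges(r), key=lambda e: (str(e[0]), str(e[1])))
        options.append(ins)
        count *= len(ins)
        if count > cap:
            raise ResourceError(f"switching count exceeds cap {cap}")
    return [Switching(tuple(combo)) for combo in itertools.product(*options)]


def _switched_descendants(n: PhyloNetwork, sw: Switching) -> dict:
    """node -> frozenset of leaf labels below it in the switched (spanning) tree."""
    keep = set(sw.choice)
    g = n.graph
    out = {}
    for v in reversed(list(nx.topological_sort(g))):
        acc = set()
        if g.out_degree(v) == 0:
            acc.add(n.labels[v])
        for w in g.successors(v):
            if n.is_reticulate(w) and (v, w) not in keep:
                continue
            acc |= out[w]
        out[v] = frozenset(acc)
    return out


def represents_hardwired(n: PhyloNetwork, c) -> bool:
    """Some tree edge's descendant leaf set in the unswitched network equals c."""
    c = frozenset(c)
    if not c <= n.leaf_labels():
        raise NetworkError(f"cluster {sorted(c)} not within leaf labels")
    desc = n.descendant_labels()
    return any(
        desc[v] == c
        for v in n.graph.nodes
        if v != n.root and n.graph.in_degree(v) <= 1
    )


def represents_softwired(n: PhyloNetwork, c, cap: int = SWITCHING_CAP) -> bool:
    """Some switching has a tree edge whose descendant leaves equal c.

    Every switching keeps one parent per reticulate node, so the switched
    graph is a spanning tree and every leaf stays reachable from the root;
    should an input ever present nodes disconnected by switching, they
    would simply contribute no labels.
    """
    c = frozenset(c)
    if not c <= n.leaf_labels():
        raise NetworkError(f"cluster {sorted(c)} not within leaf labels")
    tree_nodes = [
        v for v in n.graph.nodes if v != n.root and n.graph.in_degree(v) == 1
    ]
    for sw in switchings(n, cap):
        desc = _switched_descendants(n, sw)
        if any(desc[v] == c for v in tree_nodes):
            return True
    return False


def softwired_edge_candidates(n: PhyloNetwork, cs: ClusterSet, cap: int = SWITCHING_CAP,
                              per_cluster_cap: int | None = None) -> dict:
    """For each cluster, every tree edge that witnesses it in some switching.

    Returns ``{cluster: list of (u, v) edges}`` (deterministic order).  A
    cluster with an empty list is not represented.  ``per_cluster_cap``
    truncates the per-cluster lists (used by the bounded decomposition
    search); ``None`` keeps all.

    Descendant sets are folded over switchings as integer bitmasks over the
    leaf labels, which keeps full-network verification cheap even with many
    reticulations.
    """
    g = n.graph
    bit = {lab: 1 << i for i, lab in enumerate(sorted(n.labels.values()))}
    wanted = {}
    for c in cs.clusters:
        m = 0
        for t in c:
            if t not in bit:
                raise NetworkError(f"cluster taxon {t!r} not a leaf label")
            m |= bit[t]
        wanted[m] = frozenset(c)
    found: dict = {c: [] for c in wanted.values()}
    seen: dict = {c: set() for c in wanted.values()}
    order = list(reversed(list(nx.topological_sort(g))))
    succ = {v: sorted(g.successors(v), key=str) for v in g.nodes}
    leaf_mask = {v: bit[n.labels[v]] if v in n.labels else 0 for v in g.nodes}
    retic = set(n.reticulate_nodes())
    tree_head = [
        (next(iter(g.predecessors(v))), v)
        for v in order
        if v != n.root and g.in_degree(v) == 1
    ]
    for sw in switchings(n, cap):
        keep = set(sw.choice)
        desc = {}
        for v in order:
            acc = leaf_mask[v]
            for w in succ[v]:
                if w in retic and (v, w) not in keep:
                    continue
                acc |= desc[w]
            desc[v] = acc
        for (u, v) in tree_head:
            d = desc[v]
            if d in wanted:
                c = wanted[d]
                if (u, v) not in seen[c]:
                    seen[c].add((u, v))
                    found[c].append((u, v))
    if per_cluster_cap is not None:
        for c in found:
            found[c] = found[c][:per_cluster_cap]
    return found


def represents_all_softwired(n: PhyloNetwork, cs: ClusterSet, cap: int = SWITCHING_CAP):
    """A witness mapping epsilon: cluster -> tree edge, or None if some cluster
    is unrepresented (the first missing cluster is logged)."""
    if not cs.clusters:
        return {}
    cand = softwired_edge_candidates(n, cs, cap)
    eps = {}
    for c in sorted(cand, key=cluster_sort_key):
        if not cand[c]:
            logger.info("cluster %s not represented softwired", sorted(c))
            return None
        eps[c] = cand[c][0]
    return eps


# -- decomposition property --------------------------------------------


class DecompositionStatus(enum.Enum):
    HOLDS = "holds"
    FAILS = "fails"
    INCONCLUSIVE = "inconclusive"

    def __bool__(self):
        return self is DecompositionStatus.HOLDS


def check_decomposition(n: PhyloNetwork, cs: ClusterSet,
                        witness_cap: int = WITNESS_EDGE_CAP,
                        cap: int = SWITCHING_CAP) -> DecompositionStatus:
    """Does some witness mapping satisfy the decomposition property?

    Two clusters lie in the same connected component of the incompatibility
    graph iff their witness edges share a biconnected component of the
    underlying undirected graph.  The property quantifies existentially
    over witness mappings; the search considers up to ``witness_cap``
    alternative edges per cluster and reports INCONCLUSIVE when truncation
    could have hidden a valid assignment.
    """
    from .incompat import build_ig, components

    cs = cs.nontrivial()
    if not cs.clusters:
        return DecompositionStatus.HOLDS
    cand_full = softwired_edge_candidates(n, cs, cap)
    truncated = any(len(v) > witness_cap for v in cand_full.values())
    cand = {c: v[:witness_cap] for c, v in cand_full.items()}
    if any(not v for v in cand.values()):
        return DecompositionStatus.FAILS

    # biconnected components of the underlying undirected graph, per edge
    ug = n.graph.to_undirected()
    edge_bicomp = {}
    for i, comp_edges in enumerate(nx.biconnected_component_edges(ug)):
        for (a, b) in comp_edges:
            edge_bicomp[frozenset((a, b))] = i

    ig = build_ig(cs)
    comps = components(ig)

    # For each IG component, the bicomp ids that can host *all* its clusters.
    comp_options = []
    for comp in comps:
        shared = None
        for c in comp:
            ids = {edge_bicomp[frozenset(e)] for e in cand[c]}
            shared = ids if shared is None else shared & ids
        comp_options.append(shared or set())

    # Distinct bicomp per IG component <=> a perfect matching on the
    # components side of the bipartite compatibility graph.
    b = nx.Graph()
    left = [("comp", i) for i in range(len(comps))]
    for i, opts in enumerate(comp_options):
        b.add_node(("comp", i))
        for o in opts:
            b.add_edge(("comp", i), ("bi", o))
    matching = nx.algorithms.bipartite.maximum_matching(b, top_nodes=left) if b.edges else {}
    ok = all(("comp", i) in matching for i in range(len(comps))) if comps else True
    if ok:
        return DecompositionStatus.HOLDS
    return DecompositionStatus.INCONCLUSIVE if truncated else DecompositionStatus.FAILS


# -- maximal subtrees ---------------------------------------------------


def maximal_subtrees(n: PhyloNetwork) -> list:
    """All (node, leaf label set) where the sub-DAG below the node is a tree
    not entered from outside, and the node is highest with this property.

    Below such a node every strict descendant has indegree 1 (a reticulate
    descendant would either be entered from outside or make the sub-DAG a
    non-tree).
    """
    g = n.graph
    desc_lab = n.descendant_labels()
    treeish = {}  # all strict descendants have indegree 1
    for v in reversed(list(nx.topological_sort(g))):
        treeish[v] = all(
            treeish[w] and g.in_degree(w) == 1 for w in g.successors(v)
        )
    # a valid subtree root is a tree node; a reticulate node is entered from
    # outside by definition, so it can never root a maximal subtree
    valid = {v: treeish[v] and g.in_degree(v) <= 1 for v in g.nodes}
    out = []
    for v in g.nodes:
        if not valid[v]:
            continue
        parents = list(g.predecessors(v))
        if parents and valid[parents[0]]:
            continue  # contained in the parent's subtree
        out.append((v, desc_lab[v]))
    return sorted(out, key=lambda p: (len(p[1]), tuple(sorted(p[1]))))


# -- Hasse (containment) tree helper ------------------------------------


def hasse_tree_raw(universe: Iterable, clusters: Iterable) -> RootedTree:
    """Rooted tree on ``universe`` whose nontrivial clusters are exactly the
    given (pairwise compatible, proper, nontrivial) clusters.

    Each cluster becomes an internal node whose parent is the smallest
    cluster properly containing it (else the root); each taxon hangs under
    the smallest cluster containing it (else the root).
    """
    universe = frozenset(universe)
    cl = sorted({frozenset(c) for c in clusters if len(frozenset(c)) > 1},
                key=cluster_sort_key)
    for c in cl:
        if not c < universe:
            raise NetworkError(f"cluster {sorted(c)} not a proper subset of the universe")
    root = ("root", tuple(sorted(universe)))
    node_of = {c: ("c", tuple(sorted(c))) for c in cl}
    edges = []
    for c in cl:
        parents = [d for d in cl if c < d]
        p = node_of[min(parents, key=cluster_sort_key)] if parents else root
        edges.append((p, node_of[c]))
    leaf_labels = {}
    for t in sorted(universe):
        containing = [d for d in cl if t in d]
        p = node_of[min(containing, key=cluster_sort_key)] if containing else root
        leaf = ("leaf", t)
        edges.append((p, leaf))
        leaf_labels[leaf] = t
    if not edges:
        # single-taxon universe: a lone labelled root
        (t,) = universe
        return RootedTree([], {root: t})
    return RootedTree(edges, leaf_labels)


# -- DOT export ---------------------------------------------------------


def to_dot(n: PhyloNetwork) -> str:
    """GraphViz DOT text; reticulate nodes drawn as boxes."""
    lines = ["digraph N {"]
    ids = {v: f"n{i}" for i, v in enumerate(sorted(n.graph.nodes, key=str))}
    for v in sorted(n.graph.nodes, key=str):
        if v in n.labels:
            lines.append(f'  {ids[v]} [label="{n.labels[v]}"];')
        elif n.is_reticulate(v):
            lines.append(f'  {ids[v]} [shape=box,label=""];')
        else:
            lines.append(f'  {ids[v]} [shape=point];')
    for (u, v) in sorted(n.graph.edges, key=lambda e: (str(e[0]), str(e[1]))):
        lines.append(f"  {ids[u]} -> {ids[v]};")
    lines.append("}")
    return "\n".join(lines)
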