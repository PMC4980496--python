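"""The divide-and-conquer network construction pipeline.

Given a set of clusters (or trees to extract them from), the builder:

1. collapses maximal ST-sets into composite taxa (repeated to a fixpoint),
2. splits the incompatibility graph of the collapsed set into connected
   components,
3. solves each multi-cluster component: collapse again with respect to the
   component alone, look the simplest form up in the catalog (transferring
   the stored network by leaf relabeling), or run a bounded
   minimal-reticulation search,
4. expands composite leaves back into subtrees/subnetworks (decollapse),
5. merges component subnetworks and remaining compatible clusters over a
   containment (Hasse) backbone.

Clusters nested strictly inside a component's taxon union are distributed
into that component's collapse blocks and handled by recursion; components
whose union is nested inside another component's union are reached the same
way.  Every component subnetwork and the final network are verified against
the softwired-representation requirement; a verification or distribution
failure triggers a whole-component fallback search before giving up.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .clusters import (
    ClusterError,
    ClusterSet,
    cluster_sort_key,
    is_compatible_set,
    are_compatible,
)
from .incompat import ComponentTopology, build_ig, classify, components
from .isomorphism import SizeError, TaxonBijection, canonical_form
from .network import (
    PhyloNetwork,
    RootedTree,
    hasse_tree_raw,
    represents_all_softwired,
    reticulation_number,
)
from .simplify import CollapseResult, subtree_for_block, to_simplest

DEFAULT_MAX_R = 3
FALLBACK_TRIAL_CAP = 3_000


class ConstructError(RuntimeError):
    """Network construction failed."""


class UnsupportedComponentError(ConstructError):
    """No network within the reticulation bound was found for a component."""


class DecompositionViolation(ConstructError):
    """A cluster could not be placed consistently with the component
    decomposition (witnesses in the message)."""


# -- grafting -----------------------------------------------------------


def graft_leaves(net: PhyloNetwork, replacements: dict) -> PhyloNetwork:
    """Replace each leaf whose label is a key of ``replacements`` by the
    corresponding network's root (node namespaces kept disjoint)."""
    if not replacements:
        return net
    if net.graph.number_of_edges() == 0:
        (lab,) = net.labels.values()
        return replacements.get(lab, net)

    items = sorted(replacements.items())
    replaced_nodes = {
        net.node_of_label[lab]: (k, sub)
        for k, (lab, sub) in enumerate(items)
        if lab in net.node_of_label
    }

    def base(v):
        return ("g", v)

    def subn(k, v):
        return ("s", k, v)

    edges = []
    labels = {}
    for (u, v) in net.graph.edges:
        if v in replaced_nodes:
            k, sub = replaced_nodes[v]
            edges.append((base(u), subn(k, sub.root)))
        else:
            edges.append((base(u), base(v)))
    for v, lab in net.labels.items():
        if v not in replaced_nodes:
            labels[base(v)] = lab
    for k, (lab, sub) in enumerate(items):
        if lab not in net.node_of_label:
            raise ConstructError(f"no leaf labelled {lab!r} to graft onto")
        if sub.graph.number_of_edges() == 0:
            labels[subn(k, sub.root)] = next(iter(sub.labels.values()))
            continue
        for (u, v) in sub.graph.edges:
            edges.append((subn(k, u), subn(k, v)))
        for v, l2 in sub.labels.items():
            labels[subn(k, v)] = l2
    return PhyloNetwork(edges, labels)


# -- public spec operations --------------------------------------------


def hasse_tree(cs: ClusterSet) -> RootedTree:
    """Rooted tree whose nontrivial clusters are exactly those of the
    (pairwise compatible) input; taxa in no cluster hang below the root."""
    if not is_compatible_set(cs):
        raise ClusterError("hasse_tree requires a pairwise compatible cluster set")
    return hasse_tree_raw(cs.universe, (c for c in cs.clusters if len(c) > 1))


def transfer_network(entry_net: PhyloNetwork, g: TaxonBijection,
                     blocks: CollapseResult, cs_target: ClusterSet) -> PhyloNetwork:
    """Transfer a network between isomorphic cluster sets.

    Leaves of ``entry_net`` are relabeled through ``g`` (entry taxa to
    collapsed target taxa); every leaf that now carries a composite taxon is
    replaced by the subtree its block stands for in ``cs_target``.
    """
    gmap = g.as_dict()
    if set(gmap.keys()) != entry_net.leaf_labels():
        raise ConstructError("bijection domain does not match the entry network's leaves")
    if set(gmap.values()) != set(blocks.block_map.keys()):
        raise ConstructError("bijection image does not match the collapsed universe")
    relabeled = entry_net.copy_relabeled(gmap)
    repl = {}
    for t in relabeled.leaf_labels():
        block = blocks.block_map[t]
        if len(block) > 1:
            repl[t] = subtree_for_block(block, cs_target)
    return graft_leaves(relabeled, repl)


# -- bounded minimal-reticulation search --------------------------------


class _Assembly:
    """Mutable edge-list network under construction during the search."""

    def __init__(self, tree: RootedTree):
        self.edges = sorted(tree.graph.edges, key=lambda e: (str(e[0]), str(e[1])))
        self.labels = dict(tree.labels)
        self.root = tree.root
        self._fresh = itertools.count()
        if not self.edges:
            # single-leaf backbone: give it an explicit root
            leaf = tree.root
            top = ("fb", next(self._fresh))
            self.edges = [(top, leaf)]
            self.root = top

    def clone(self):
        new = object.__new__(_Assembly)
        new.edges = list(self.edges)
        new.labels = dict(self.labels)
        new.root = self.root
        new._fresh = itertools.count(next(self._fresh) * 1000 + 999)
        return new

    def fresh(self):
        return ("fb", next(self._fresh))

    def subdivide(self, edge):
        """Split (u, v) into (u, w), (w, v); return w."""
        u, v = edge
        w = self.fresh()
        i = self.edges.index((u, v))
        self.edges[i] = (u, w)
        self.edges.append((w, v))
        return w

    def new_root(self):
        w = self.fresh()
        self.edges.append((w, self.root))
        self.root = w
        return w

    def add_edge(self, u, v):
        self.edges.append((u, v))

    def add_leaf(self, parent, label):
        leaf = ("fbleaf", label)
        self.edges.append((parent, leaf))
        self.labels[leaf] = label
        return leaf

    def build(self) -> PhyloNetwork:
        return PhyloNetwork(self.edges, self.labels)


def _restricted_backbone(cs: ClusterSet, removed: frozenset):
    """Hasse backbone on the remaining taxa, or None if the restriction is
    incompatible.  Clusters covering all remaining taxa are left out of the
    backbone (they are handled by attachment sites above the root)."""
    rest = cs.universe - removed
    if not rest:
        return None
    restricted = {c - removed for c in cs.clusters}
    restricted = {c for c in restricted if c and c != rest and len(c) > 1}
    cl = sorted(restricted, key=cluster_sort_key)
    for i, a in enumerate(cl):
        for b in cl[i + 1:]:
            if not are_compatible(a, b):
                return None
    return hasse_tree_raw(rest, cl)


def _guided_attach(cs: ClusterSet, removed: tuple, escapes: bool) -> PhyloNetwork | None:
    """Heuristic reattachment around *site chains*.

    Clusters meeting the removed set are grouped by their restriction base
    (the cluster minus the removed taxa); each group becomes a chain of
    attachment nodes stacked on the edge representing the base, ordered so
    that clusters with smaller removed parts sit lower.  A removed taxon
    gets one parent per chain, at the lowest chain node whose cluster
    contains it.  With ``escapes`` every removed taxon additionally gets a
    parent at a node above the root, so it can be switched out of any
    cluster that must exclude it — this costs one reticulation per taxon
    but makes every cluster representable along its chain.
    """
    removed_set = frozenset(removed)
    backbone = _restricted_backbone(cs, removed_set)
    if backbone is None:
        return None
    rest = cs.universe - removed_set
    asm = _Assembly(backbone)
    desc = backbone.descendant_labels() if backbone.graph.number_of_edges() else {
        backbone.root: frozenset(backbone.labels.values())
    }
    edge_of_desc = {}
    for (u, v) in list(asm.edges):
        edge_of_desc[desc.get(v, frozenset())] = (u, v)

    touched = [c for c in cs.sorted_clusters() if c & removed_set]
    groups: dict = {}
    for c in touched:
        groups.setdefault(c - removed_set, []).append(c)

    site_of_cluster = {}
    for base in sorted(groups, key=cluster_sort_key):
        # lower chain positions for smaller removed parts
        chain = sorted(groups[base],
                       key=lambda c: (len(c & removed_set), cluster_sort_key(c)))
        for c in chain:
            if not base:
                node = asm.fresh()
                asm.add_edge(asm.root, node)
                site_of_cluster[c] = node
            elif base == rest:
                site_of_cluster[c] = asm.new_root()
            else:
                edge = edge_of_desc.get(base)
                if edge is None:
                    return None
                w = asm.subdivide(edge)
                edge_of_desc[base] = (edge[0], w)  # next site stacks above
                site_of_cluster[c] = w

    escape_node = asm.new_root() if escapes else None
    for t in sorted(removed_set):
        parents = []
        for base in sorted(groups, key=cluster_sort_key):
            chain = sorted(groups[base],
                           key=lambda c: (len(c & removed_set), cluster_sort_key(c)))
            if base:
                # one parent per chain, at the lowest cluster containing t
                for c in chain:
                    if t in c:
                        parents.append(site_of_cluster[c])
                        break
            else:
                # base-empty groups are independent single nodes
                for c in chain:
                    if t in c:
                        parents.append(site_of_cluster[c])
        if escapes:
            parents.append(escape_node)
        if not parents:
            return None
        if len(parents) == 1:
            asm.add_leaf(parents[0], t)
        else:
            h = asm.fresh()
            for p in parents:
                asm.add_edge(p, h)
            asm.add_leaf(h, t)
    try:
        return asm.build()
    except Exception:
        return None


def _attachment_search(cs: ClusterSet, removed: tuple, indegs: tuple,
                       trial_budget: list) -> PhyloNetwork | None:
    """Exhaustive reattachment: removed taxa in order, each below a new
    reticulate node whose parents subdivide chosen edges (TOP = above the
    current root); deterministic order, bounded by ``trial_budget``."""
    backbone = _restricted_backbone(cs, frozenset(removed))
    if backbone is None:
        return None

    def rec(asm: _Assembly, i: int):
        if i == len(removed):
            if trial_budget[0] <= 0:
                return None
            trial_budget[0] -= 1
            try:
                net = asm.build()
            except Exception:
                return None
            if represents_all_softwired(net, cs) is not None:
                return net
            return None
        t, k = removed[i], indegs[i]
        options = list(range(len(asm.edges) + 1))  # index len == TOP
        for combo in itertools.combinations_with_replacement(options, k):
            if trial_budget[0] <= 0:
                return None
            child = asm.clone()
            edge_snapshot = list(child.edges)
            parents = []
            for idx in combo:
                if idx == len(edge_snapshot):
                    parents.append(child.new_root())
                else:
                    parents.append(child.subdivide(tuple(edge_snapshot[idx])))
                    # re-resolve: after subdividing, the lower half keeps the
                    # original head, so repeated picks of the same index
                    # stack chains deterministically
                    edge_snapshot[idx] = (parents[-1], edge_snapshot[idx][1])
            if k == 1:
                child.add_leaf(parents[0], t)
            else:
                h = child.fresh()
                for p in parents:
                    child.add_edge(p, h)
                child.add_leaf(h, t)
            res = rec(child, i + 1)
            if res is not None:
                return res
        return None

    return rec(_Assembly(backbone), 0)


def _compositions(total: int, parts: int):
    """Ordered compositions of ``total`` into ``parts`` positive integers."""
    if parts == 1:
        yield (total,)
        return
    for first in range(1, total - parts + 2):
        for restc in _compositions(total - first, parts - 1):
            yield (first,) + restc


def fallback_search(cs: ClusterSet, max_r: int = DEFAULT_MAX_R,
                    trial_cap: int = FALLBACK_TRIAL_CAP) -> PhyloNetwork:
    """A network representing an incompatible simplest cluster set softwired,
    with at most ``max_r`` reticulations (sum of indeg-1).

    Taxon-removal sets are tried in order of increasing size then
    lexicographically.  A guided pass places reticulation parents on the
    edges representing each cluster's restriction; an exhaustive pass then
    looks for strictly fewer reticulations below the guided optimum, within
    a bounded number of trials.
    """
    if is_compatible_set(cs):
        raise ClusterError("fallback_search expects an incompatible cluster set")
    taxa = sorted(cs.universe)
    n = len(taxa)

    best = None  # (r, order, net)
    order = 0
    for s in range(1, n):
        for removal in itertools.combinations(taxa, s):
            for escapes in (False, True):
                order += 1
                net = _guided_attach(cs, removal, escapes)
                if net is None:
                    continue
                r = reticulation_number(net)
                if r > max_r or (best is not None and r >= best[0]):
                    continue
                if represents_all_softwired(net, cs) is None:
                    continue
                if best is None or (r, order) < (best[0], best[1]):
                    best = (r, order, net)

    upper = best[0] if best else max_r + 1
    for r in range(1, upper):
        budget = [trial_cap]
        for s in range(1, min(r, n - 1) + 1):
            for removal in itertools.combinations(taxa, s):
                for extra in _compositions(r, s):
                    indegs = tuple(e + 1 for e in extra)
                    net = _attachment_search(cs, removal, indegs, budget)
                    if net is not None:
                        return net
    if best is not None:
        return best[2]
    raise UnsupportedComponentError(
        f"no network with at most {max_r} reticulations found for {cs!r}"
    )


# -- runtime catalog memo ----------------------------------------------

_runtime_memo: dict = {}


def clear_memo():
    _runtime_memo.clear()


def _solve_simplest(simp: ClusterSet, max_r: int, trial_cap: int):
    """Network for a simplest incompatible set: catalog hit, runtime memo of
    a previous isomorphic solve, or fresh fallback search.  Returns
    (network over simp's taxa, method tag)."""
    from .catalog import lookup

    hit = lookup(simp) if len(simp.clusters) in (2, 3) else None
    if hit is not None:
        entry, g = hit
        return entry.network.copy_relabeled(g.as_dict()), f"catalog:{entry.name}"
    try:
        key, perm = canonical_form(simp)
    except SizeError:
        key = perm = None
    if key is not None and key in _runtime_memo:
        canon_net = _runtime_memo[key]
        inv = {f"p{pos}": t for t, pos in perm.items()}
        return canon_net.copy_relabeled(inv), "memo"
    net = fallback_search(simp, max_r, trial_cap)
    if key is not None:
        _runtime_memo[key] = net.copy_relabeled({t: f"p{pos}" for t, pos in perm.items()})
    return net, "fallback"


# -- the pipeline -------------------------------------------------------


@dataclass
class ComponentReport:
    clusters: ClusterSet
    topology: ComponentTopology
    method: str
    reticulations: int
    depth: int


@dataclass
class BuildResult:
    network: PhyloNetwork
    per_component: list = field(default_factory=list)
    witness: dict | None = None

    def top_components(self):
        return [c for c in self.per_component if c.depth == 0]


_top_counter = itertools.count()


def _attach_at_root(core: PhyloNetwork, loose, new_root: bool) -> PhyloNetwork:
    """Hang extra leaves below the root; ``new_root`` inserts a fresh root
    above the core first (needed when an edge into the old root must exist)."""
    loose = sorted(loose)
    if not loose and not new_root:
        return core
    edges = list(core.graph.edges)
    labels = dict(core.labels)
    root = core.root
    if new_root or not edges:
        top = ("top", next(_top_counter))
        edges.append((top, core.root))
        root = top
    for t in loose:
        leaf = ("loose", t)
        edges.append((root, leaf))
        labels[leaf] = t
    return PhyloNetwork(edges, labels)


def _build_in(clusters, universe: frozenset, max_r: int, trial_cap: int,
              accounting: list, depth: int) -> PhyloNetwork:
    """Network over ``universe`` for nontrivial clusters strictly inside it.

    Taxa outside every cluster hang below the root.  A cluster equal to the
    union of all clusters (a *spanning* cluster) cannot live in a
    union-universe ClusterSet; it is peeled off and represented by the edge
    into the root of the network built for the remaining clusters.
    """
    clusters = sorted({c for c in clusters if len(c) > 1}, key=cluster_sort_key)
    for c in clusters:
        if not c <= universe:
            raise ConstructError(
                f"cluster {sorted(c)} is not inside {sorted(universe)}"
            )
    if not clusters:
        return hasse_tree_raw(universe, [])
    covered = frozenset().union(*clusters)
    spans = [c for c in clusters if c == covered]
    if spans:
        # represented by the edge into the core root (new_root below)
        core = _build_in([c for c in clusters if c != covered], covered,
                         max_r, trial_cap, accounting, depth)
        # the edge onto the core root represents the spanning cluster
        return _attach_at_root(core, universe - covered, new_root=True)
    core = _build_rec(ClusterSet(covered, frozenset(clusters)), max_r,
                      trial_cap, accounting, depth)
    return _attach_at_root(core, universe - covered, new_root=False)


def _component_net(kset: list, inside: list, universe_k: frozenset, max_r: int,
                   trial_cap: int, accounting: list, depth: int) -> PhyloNetwork:
    """Subnetwork for one multi-cluster IG component ``kset`` with the
    clusters nested strictly inside its taxon union distributed into its
    collapse blocks."""
    comp_cs = ClusterSet(universe_k, frozenset(kset))
    res = to_simplest(comp_cs)
    simp = res.collapsed
    ig = build_ig(simp)
    comps = components(ig)
    topo = classify(comps[0], ig) if len(comps) == 1 else ComponentTopology.OTHER
    net0, method = _solve_simplest(simp, max_r, trial_cap)

    placed = set()
    repl = {}
    for t in sorted(simp.universe):
        block = res.block_map[t]
        if len(block) <= 1:
            continue
        inner = [c for c in inside if c < block]
        placed.update(inner)
        repl[t] = _build_in(inner, block, max_r, trial_cap, accounting, depth + 1)
    blocks = set(res.block_map.values())
    for c in inside:
        if c in placed or c in blocks or c in set(kset):
            continue
        raise DecompositionViolation(
            f"cluster {sorted(c)} is nested in component union {sorted(universe_k)} "
            "but fits no collapse block"
        )
    net = graft_leaves(net0, repl)
    if represents_all_softwired(net, ClusterSet(universe_k, frozenset(kset) | frozenset(inside))) is None:
        raise DecompositionViolation(
            f"component subnetwork fails softwired verification for "
            f"{sorted(map(sorted, kset))}"
        )
    accounting.append(ComponentReport(comp_cs, topo, method,
                                      reticulation_number(net), depth))
    return net


def _component_monolithic(kset: list, inside: list, universe_k: frozenset,
                          max_r: int, trial_cap: int, accounting: list,
                          depth: int) -> PhyloNetwork:
    """Safety net: solve the component together with its nested clusters as
    one collapsed problem."""
    all_cl = frozenset(kset) | frozenset(inside)
    cs = ClusterSet(universe_k, all_cl)
    res = to_simplest(cs)
    net0, method = _solve_simplest(res.collapsed, max_r, trial_cap)
    repl = {}
    for t in sorted(res.collapsed.universe):
        block = res.block_map[t]
        if len(block) > 1:
            inner = [c for c in all_cl if c < block]
            repl[t] = _build_in(inner, block, max_r, trial_cap, accounting, depth + 1)
    net = graft_leaves(net0, repl)
    if represents_all_softwired(net, cs) is None:
        raise ConstructError(
            f"monolithic fallback failed verification for {cs!r}"
        )
    accounting.append(ComponentReport(cs, ComponentTopology.OTHER,
                                      method + "+monolithic",
                                      reticulation_number(net), depth))
    return net


def _build_rec(cs: ClusterSet, max_r: int, trial_cap: int,
               accounting: list, depth: int = 0) -> PhyloNetwork:
    """Recursive core; ``cs`` holds nontrivial clusters with universe equal
    to their union."""
    if is_compatible_set(cs):
        return hasse_tree_raw(cs.universe, cs.clusters)
    res = to_simplest(cs)
    col = res.collapsed

    ig = build_ig(col)
    comps = components(ig)
    multi = [c for c in comps if len(c) > 1]
    singles = [c[0] for c in comps if len(c) == 1]
    supers = {i: frozenset().union(*k) for i, k in enumerate(multi)}
    top = [i for i in supers
           if not any(supers[i] < supers[j] for j in supers if j != i)]

    # pairwise compatibility of the merge family is a theorem of the
    # decomposition; assert it with witnesses rather than assume silently
    family = [supers[i] for i in top] + [
        s for s in singles if not any(s <= supers[i] for i in top)
    ]
    for a, b in itertools.combinations(sorted(family, key=cluster_sort_key), 2):
        if not are_compatible(a, b):
            raise DecompositionViolation(
                f"merge family incompatible: {sorted(a)} vs {sorted(b)}"
            )

    subnets = {}
    for i in top:
        uk = supers[i]
        kset = multi[i]
        inside = [c for c in col.clusters
                  if c < uk and c not in set(kset)]
        try:
            subnets[i] = _component_net(kset, inside, uk, max_r, trial_cap,
                                        accounting, depth)
        except (DecompositionViolation, UnsupportedComponentError):
            subnets[i] = _component_monolithic(kset, inside, uk, max_r,
                                               trial_cap, accounting, depth)

    # merge over a Hasse backbone with one placeholder taxon per component
    if len(top) == 1 and supers[top[0]] == col.universe:
        merged = subnets[top[0]]
    else:
        placeholder = {}
        for i in top:
            name = f"comp{i}"
            while name in col.universe:
                name += "x"
            placeholder[i] = name
        covered = frozenset().union(*(supers[i] for i in top)) if top else frozenset()
        reduced_universe = (col.universe - covered) | frozenset(placeholder.values())

        def reduce_cluster(c):
            out = set(c - covered)
            for i in top:
                if supers[i] <= c:
                    out.add(placeholder[i])
                elif supers[i] & c:
                    raise DecompositionViolation(
                        f"cluster {sorted(c)} straddles component union {sorted(supers[i])}"
                    )
            return frozenset(out)

        backbone_clusters = set()
        for s in family:
            if s in supers.values():
                continue
            rc = reduce_cluster(s)
            if len(rc) > 1 and rc != reduced_universe:
                backbone_clusters.add(rc)
        backbone = hasse_tree_raw(reduced_universe, backbone_clusters)
        merged = graft_leaves(
            backbone, {placeholder[i]: subnets[i] for i in top}
        )

    # decollapse the blocks of this level's global collapse: each block's
    # restriction is compatible by the ST-set definition, so blocks expand
    # to subtrees
    repl = {}
    for t in sorted(col.universe):
        block = res.block_map.get(t, frozenset([t]))
        if len(block) > 1:
            inner = [c for c in cs.clusters if c < block]
            repl[t] = hasse_tree_raw(block, inner)
    return graft_leaves(merged, repl)


def build_component(cs_comp: ClusterSet, max_r: int = DEFAULT_MAX_R,
                    trial_cap: int = FALLBACK_TRIAL_CAP) -> PhyloNetwork:
    """Subnetwork for the clusters of one incompatibility-graph component."""
    acc: list = []
    kset = sorted(cs_comp.clusters, key=cluster_sort_key)
    return _component_net(kset, [], cs_comp.union, max_r, trial_cap, acc, 0)


def merge(subnets: list, singles, universe) -> PhyloNetwork:
    """Merge component subnetworks and leftover compatible clusters.

    ``subnets`` is a list of (component ClusterSet, PhyloNetwork); the union
    of each component's taxa becomes a super-cluster that must be compatible
    with everything else (asserted), and each super-cluster's position in
    the containment backbone is taken by the subnetwork's root.
    """
    universe = frozenset(universe)
    singles = [frozenset(s) for s in singles]
    supers = [(cs.union, net) for cs, net in subnets]
    family = [u for u, _ in supers] + [s for s in singles if len(s) > 1]
    for a, b in itertools.combinations(family, 2):
        if not are_compatible(a, b):
            raise DecompositionViolation(
                f"merge family incompatible: {sorted(a)} vs {sorted(b)}"
            )
    placeholder = {}
    for i, (u, _) in enumerate(supers):
        name = f"comp{i}"
        while name in universe:
            name += "x"
        placeholder[i] = name
    covered = frozenset().union(*(u for u, _ in supers)) if supers else frozenset()
    reduced_universe = (universe - covered) | frozenset(placeholder.values())
    backbone_clusters = set()
    for s in singles:
        if len(s) <= 1 or s in (u for u, _ in supers):
            continue
        out = set(s - covered)
        for i, (u, _) in enumerate(supers):
            if u <= s:
                out.add(placeholder[i])
            elif u & s:
                raise DecompositionViolation(
                    f"cluster {sorted(s)} straddles component union {sorted(u)}"
                )
        rc = frozenset(out)
        if len(rc) > 1 and rc != reduced_universe:
            backbone_clusters.add(rc)
    backbone = hasse_tree_raw(reduced_universe, backbone_clusters)
    return graft_leaves(
        backbone, {placeholder[i]: net for i, (_, net) in enumerate(supers)}
    )


def build_network(source, max_r: int = DEFAULT_MAX_R,
                  trial_cap: int = FALLBACK_TRIAL_CAP) -> BuildResult:
    """Build a rooted phylogenetic network representing every input cluster
    in the softwired sense.

    ``source`` is a ClusterSet or a list of RootedTree (whose nontrivial
    clusters are pooled).  The result is verified: a witness edge mapping is
    computed for the full input, and the reticulation identity is checked.
    """
    if isinstance(source, ClusterSet):
        cs = source
    else:
        trees = list(source)
        if not trees:
            raise ClusterError("empty input")
        from .clusters import clusters_of_tree

        universe = frozenset().union(*(t.leaf_labels() for t in trees))
        clusters = frozenset().union(
            *(clusters_of_tree(t).clusters for t in trees)
        )
        cs = ClusterSet(universe, clusters)
    if not cs.universe:
        raise ClusterError("empty taxon universe")
    nt = cs.nontrivial()
    accounting: list = []
    if not nt.clusters:
        net = hasse_tree_raw(cs.universe, [])
    else:
        net = _build_in(nt.clusters, cs.universe, max_r, trial_cap, accounting, 0) \
            if nt.union != cs.universe or any(c == nt.union for c in nt.clusters) \
            else _build_rec(ClusterSet(nt.union, nt.clusters), max_r, trial_cap, accounting, 0)
    witness = represents_all_softwired(net, nt if nt.universe == cs.universe
                                       else ClusterSet(cs.universe, nt.clusters))
    if witness is None and nt.clusters:
        raise ConstructError("built network fails softwired verification")
    reticulation_number(net)  # identity asserted inside
    return BuildResult(net, accounting, witness)
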