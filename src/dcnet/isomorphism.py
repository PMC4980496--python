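"""Cluster-set isomorphism, canonical keys, and network isomorphism.

Two cluster sets are isomorphic when, after collapsing all maximal ST-sets,
a bijection between the reduced universes carries one cluster family onto
the other.  (Read literally, the published co-membership phrasing only
constrains *pairs* of taxa, under which {{1,2,3}} and {{1,2},{1,3},{2,3}}
would coincide; the network-transfer argument relabels leaves cluster-for-
cluster, so the strong family-bijection reading is the default and the weak
pairwise reading is available behind ``strong=False``.)

Canonical keys: a simplest cluster set is encoded under its minimal taxon
relabeling, searched over permutations pruned by taxon signatures (the
multiset of sizes of clusters containing the taxon).  Signatures are
isomorphism-invariant, so restricting the search to signature-preserving
permutations still yields equal keys exactly for isomorphic sets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx

from .clusters import ClusterSet, union_universe
from .network import PhyloNetwork
from .simplify import to_simplest

CANONICAL_BOUND = 10  # largest universe for canonical-key permutation search


class SizeError(ValueError):
    """Universe too large for exhaustive canonicalization; test isomorphism
    directly with :func:`clustersets_isomorphic`."""


@dataclass(frozen=True)
class TaxonBijection:
    """A one-to-one mapping between two taxon universes."""

    pairs: tuple  # tuple of (source, target)

    def as_dict(self) -> dict:
        return dict(self.pairs)

    def __getitem__(self, t):
        return self.as_dict()[t]

    def inverse(self) -> "TaxonBijection":
        return TaxonBijection(tuple(sorted((b, a) for a, b in self.pairs)))


@dataclass(frozen=True)
class CanonicalKey:
    encoding: str


# -- mask machinery -----------------------------------------------------


def _to_masks(cs: ClusterSet):
    """(sorted taxa list, list of int bitmask clusters)."""
    taxa = sorted(cs.universe)
    idx = {t: i for i, t in enumerate(taxa)}
    masks = sorted(
        sum(1 << idx[t] for t in c) for c in cs.clusters
    )
    return taxa, masks


def _signatures(masks, n):
    """Taxon signature: sorted sizes of the clusters containing it."""
    sizes = [bin(m).count("1") for m in masks]
    sig = []
    for i in range(n):
        sig.append(tuple(sorted(sizes[k] for k, m in enumerate(masks) if (m >> i) & 1)))
    return sig


def _signature_groups(masks, n):
    """Taxon indices grouped by signature; groups ordered by signature."""
    sig = _signatures(masks, n)
    groups: dict = {}
    for i in range(n):
        groups.setdefault(sig[i], []).append(i)
    return sorted(groups.items())


def _candidate_perms(masks_a, masks_b, n):
    """Signature-consistent bijections a-index -> b-index (lazy)."""
    ga = _signature_groups(masks_a, n)
    gb = _signature_groups(masks_b, n)
    if [(s, len(m)) for (s, m) in ga] != [(s, len(m)) for (s, m) in gb]:
        return
    for combo in itertools.product(*[itertools.permutations(mb) for (_, mb) in gb]):
        perm = [0] * n
        for (sig_a, mem_a), mem_b in zip(ga, combo):
            for i, j in zip(mem_a, mem_b):
                perm[i] = j
        yield perm


def _apply_perm(masks, perm):
    out = []
    for m in masks:
        x = 0
        i = 0
        while m:
            if m & 1:
                x |= 1 << perm[i]
            m >>= 1
            i += 1
        out.append(x)
    return tuple(sorted(out))


def _position_perms(masks, n):
    """Relabelings to canonical positions: taxa grouped by signature, the
    groups (ordered by signature) occupying consecutive position blocks,
    all permutations within each block."""
    groups = _signature_groups(masks, n)
    blocks = []
    start = 0
    for _, members in groups:
        blocks.append((members, range(start, start + len(members))))
        start += len(members)
    for combo in itertools.product(
        *[itertools.permutations(positions) for (_, positions) in blocks]
    ):
        perm = [0] * n
        for (members, _), pos_tuple in zip(blocks, combo):
            for i, p in zip(members, pos_tuple):
                perm[i] = p
        yield perm


def canonical_masks(masks, n):
    """Minimal encoding over signature-consistent relabelings.

    Returns (encoding tuple, permutation old-index -> canonical position).
    Signatures are isomorphism-invariant, so isomorphic mask families reach
    identical minimal encodings.
    """
    best = None
    best_perm = None
    for perm in _position_perms(masks, n):
        enc = _apply_perm(masks, perm)
        if best is None or enc < best:
            best, best_perm = enc, perm
    return best, best_perm


def canonical_form(cs: ClusterSet):
    """(CanonicalKey, mapping taxon -> canonical position) for a simplest set."""
    union_universe(cs)
    n = len(cs.universe)
    if n > CANONICAL_BOUND:
        raise SizeError(
            f"universe of {n} taxa exceeds the canonicalization bound "
            f"{CANONICAL_BOUND}; use clustersets_isomorphic directly"
        )
    taxa, masks = _to_masks(cs)
    enc, perm = canonical_masks(masks, n)
    key = CanonicalKey(f"n={n};" + ";".join(
        ",".join(str(i) for i in range(n) if (m >> i) & 1) for m in enc
    ))
    return key, {taxa[i]: perm[i] for i in range(n)}


def canonical_key(cs: ClusterSet) -> CanonicalKey:
    return canonical_form(cs)[0]


# -- cluster-set isomorphism -------------------------------------------


def _weak_candidate_perms(masks_a, masks_b, n):
    """Bijections consistent with co-membership degree (the only invariant
    available under the weak, pairwise reading)."""
    def groups(masks):
        com = _comember_masks(masks, n)
        out: dict = {}
        for i in range(n):
            out.setdefault(bin(com[i]).count("1"), []).append(i)
        return sorted(out.items())

    ga, gb = groups(masks_a), groups(masks_b)
    if [(d, len(m)) for d, m in ga] != [(d, len(m)) for d, m in gb]:
        return
    for combo in itertools.product(*[itertools.permutations(mb) for (_, mb) in gb]):
        perm = [0] * n
        for (_, mem_a), mem_b in zip(ga, combo):
            for i, j in zip(mem_a, mem_b):
                perm[i] = j
        yield perm


def _comember_masks(masks, n):
    """For each taxon, the set of taxa sharing at least one cluster with it."""
    out = [0] * n
    for m in masks:
        for i in range(n):
            if (m >> i) & 1:
                out[i] |= m
    return out


def clustersets_isomorphic(a: ClusterSet, b: ClusterSet, strong: bool = True):
    """A TaxonBijection between the collapsed universes, or None.

    Both inputs are reduced to their simplest forms first.  ``strong``
    requires the bijection to map cluster families onto each other;
    ``strong=False`` only preserves pairwise co-membership of taxa.
    """
    ra, rb = to_simplest(union_universe(a)), to_simplest(union_universe(b))
    sa, sb = ra.collapsed, rb.collapsed
    na, nb = len(sa.universe), len(sb.universe)
    if na != nb:
        return None
    if strong and len(sa.clusters) != len(sb.clusters):
        return None
    taxa_a, masks_a = _to_masks(sa)
    taxa_b, masks_b = _to_masks(sb)
    target = tuple(sorted(masks_b))
    com_a = _comember_masks(masks_a, na)
    com_b = _comember_masks(masks_b, nb)
    candidates = (_candidate_perms(masks_a, masks_b, na) if strong
                  else _weak_candidate_perms(masks_a, masks_b, na))
    for perm in candidates:
        if strong:
            if _apply_perm(masks_a, perm) == target:
                return TaxonBijection(tuple(sorted(
                    (taxa_a[i], taxa_b[perm[i]]) for i in range(na)
                )))
        else:
            ok = True
            for i in range(na):
                mapped = 0
                m = com_a[i]
                k = 0
                while m:
                    if m & 1:
                        mapped |= 1 << perm[k]
                    m >>= 1
                    k += 1
                if mapped != com_b[perm[i]]:
                    ok = False
                    break
            if ok:
                return TaxonBijection(tuple(sorted(
                    (taxa_a[i], taxa_b[perm[i]]) for i in range(na)
                )))
    return None


# -- network isomorphism -----------------------------------------------


def networks_isomorphic(n1: PhyloNetwork, n2: PhyloNetwork) -> bool:
    """Directed-graph isomorphism preserving leaf labels."""
    if n1.leaf_labels() != n2.leaf_labels():
        return False

    def tagged(n):
        g = nx.DiGraph()
        g.add_nodes_from((v, {"label": n.labels.get(v)}) for v in n.graph.nodes)
        g.add_edges_from(n.graph.edges())
        return g

    return nx.is_isomorphic(
        tagged(n1), tagged(n2),
        node_match=nx.algorithms.isomorphism.categorical_node_match("label", None),
    )
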