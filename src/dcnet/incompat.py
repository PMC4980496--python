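"""The incompatibility graph IG(C): one node per cluster, edges between
incompatible pairs.  Its connected components drive the divide-and-conquer
construction; components with 2 or 3 clusters are classified for catalog
dispatch (PAIR, PATH3, TRIANGLE3)."""

from __future__ import annotations

import enum

import networkx as nx

from .clusters import ClusterSet, are_compatible, cluster_sort_key


class ComponentTopology(enum.Enum):
    SINGLETON = "singleton"
    PAIR = "pair"          # 2 nodes, 1 edge
    PATH3 = "path3"        # 3 nodes, 2 edges
    TRIANGLE3 = "triangle3"  # 3 nodes, 3 edges
    OTHER = "other"


def build_ig(cs: ClusterSet) -> nx.Graph:
    """Undirected graph on the clusters of ``cs``; edges join incompatible pairs.

    Trivial clusters are compatible with everything and are expected to be
    stripped upstream; if present they simply become isolated nodes.
    """
    g = nx.Graph()
    cl = cs.sorted_clusters()
    g.add_nodes_from(cl)
    for i, a in enumerate(cl):
        for b in cl[i + 1:]:
            if not are_compatible(a, b):
                g.add_edge(a, b)
    return g


def components(ig: nx.Graph) -> list:
    """Connected components as sorted cluster lists, in deterministic order."""
    comps = [sorted(c, key=cluster_sort_key) for c in nx.connected_components(ig)]
    return sorted(comps, key=lambda c: cluster_sort_key(c[0]))


def classify(component, ig: nx.Graph) -> ComponentTopology:
    """Topology tag of one connected component of ``ig``."""
    nodes = list(component)
    k = len(nodes)
    m = ig.subgraph(nodes).number_of_edges()
    if k == 1:
        return ComponentTopology.SINGLETON
    if k == 2 and m == 1:
        return ComponentTopology.PAIR
    if k == 3 and m == 2:
        return ComponentTopology.PATH3
    if k == 3 and m == 3:
        return ComponentTopology.TRIANGLE3
    return ComponentTopology.OTHER


def path3_middle(component, ig: nx.Graph):
    """The unique degree-2 cluster of a PATH3 component."""
    sub = ig.subgraph(component)
    mids = [v for v in sub.nodes if sub.degree(v) == 2]
    if len(mids) != 1:
        raise ValueError("component is not a 3-node path")
    return mids[0]


def to_dot(ig: nx.Graph) -> str:
    """DOT export of the incompatibility graph for inspection."""
    name = {c: "{" + ",".join(sorted(c)) + "}" for c in ig.nodes}
    lines = ["graph IG {"]
    for c in sorted(ig.nodes, key=cluster_sort_key):
        lines.append(f'  "{name[c]}";')
    for a, b in sorted(ig.edges, key=lambda e: (cluster_sort_key(e[0]), cluster_sort_key(e[1]))):
        if cluster_sort_key(a) > cluster_sort_key(b):
            a, b = b, a
        lines.append(f'  "{name[a]}" -- "{name[b]}";')
    lines.append("}")
    return "\n".join(lines)
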