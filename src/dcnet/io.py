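"""Readers and writers for the plain-text cluster format and (e)Newick.

Cluster files: UTF-8; ``#``-prefixed comment lines ignored; an optional
first data line ``taxa: a,b,c`` fixes the universe; every other non-blank
line is one cluster as comma-separated labels.  Duplicate cluster lines
collapse with a logged warning.
"""

from __future__ import annotations

import logging
from pathlib import Path

import dendropy

from .clusters import ClusterError, ClusterSet, validate_label
from .enewick import parse_enewick, write_enewick as _render_enewick
from .network import PhyloNetwork, RootedTree

logger = logging.getLogger(__name__)


def parse_clusters_text(text: str, source: str = "<string>") -> ClusterSet:
    universe = None
    clusters = []
    seen = set()
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.lower().startswith("taxa:"):
            if universe is not None or clusters:
                raise ClusterError(
                    f"{source}:{lineno}: 'taxa:' line must come first and appear once"
                )
            universe = _parse_labels(line[5:], source, lineno)
            continue
        members = _parse_labels(line, source, lineno)
        c = frozenset(members)
        if c in seen:
            logger.warning("%s:%d: duplicate cluster %s ignored", source, lineno, sorted(c))
            continue
        seen.add(c)
        clusters.append(c)
    if universe is None:
        universe = frozenset().union(*clusters) if clusters else frozenset()
    else:
        universe = frozenset(universe)
    if not universe:
        raise ClusterError(f"{source}: no taxa found")
    return ClusterSet(universe, frozenset(clusters))


def _parse_labels(chunk: str, source: str, lineno: int):
    labels = []
    for tok in chunk.split(","):
        tok = tok.strip()
        if not tok:
            raise ClusterError(f"{source}:{lineno}: empty taxon label")
        labels.append(validate_label(tok))
    if len(set(labels)) != len(labels):
        raise ClusterError(f"{source}:{lineno}: repeated taxon within one cluster")
    return labels


def read_clusters(path) -> ClusterSet:
    p = Path(path)
    return parse_clusters_text(p.read_text(), str(p))


def write_clusters(cs: ClusterSet, path) -> None:
    lines = ["taxa: " + ",".join(sorted(cs.universe))]
    for c in cs.sorted_clusters():
        lines.append(",".join(sorted(c)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_newick(path) -> list:
    """Rooted trees, one Newick string per line; internal node labels and
    branch lengths are ignored."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        try:
            dtree = dendropy.Tree.get(data=line, schema="newick")
        except Exception as exc:
            raise ClusterError(f"{path}:{lineno}: newick parse error: {exc}") from exc
        out.append(_from_dendropy(dtree))
    return out


def _from_dendropy(dtree: "dendropy.Tree") -> RootedTree:
    edges = []
    labels = {}
    for node in dtree.preorder_node_iter():
        for child in node.child_nodes():
            edges.append((id(node), id(child)))
        if node.is_leaf():
            name = node.taxon.label if node.taxon else None
            if not name:
                raise ClusterError("unlabelled leaf in newick input")
            labels[id(node)] = name.replace(" ", "_")
    if not edges:
        return RootedTree([], labels)
    return RootedTree(edges, labels)


def read_enewick(path) -> PhyloNetwork:
    return parse_enewick(Path(path).read_text())


def write_enewick(n: PhyloNetwork, path) -> None:
    Path(path).write_text(_render_enewick(n) + "\n")
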