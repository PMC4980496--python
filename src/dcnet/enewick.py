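"""Extended Newick (eNewick) reader and writer for rooted networks.

Dialect: reticulate (hybrid) nodes carry ``#H<k>`` tags.  The first
occurrence of a tag may bring children and an optional leaf label;
subsequent occurrences are bare references, e.g.::

    ((1,(2)#H1),(#H1,3));

is the one-reticulation network in which leaf 2 has two parents.  Branch
lengths and internal node labels are accepted and ignored.
"""

from __future__ import annotations

import itertools
import re

from .network import PhyloNetwork, RootedTree


class ENewickError(ValueError):
    """Malformed (e)Newick input."""


_LABEL_END = set("(),;")


def parse_enewick(text: str) -> PhyloNetwork:
    """Parse one eNewick string into a PhyloNetwork."""
    s = text.strip()
    if not s:
        raise ENewickError("empty input")
    if s.endswith(";"):
        s = s[:-1]
    pos = 0
    fresh = itertools.count()
    hybrid_of_tag: dict = {}
    children: dict = {}
    labels: dict = {}

    def error(msg):
        raise ENewickError(f"{msg} at position {pos}: {text!r}")

    def parse_node():
        nonlocal pos
        kids = []
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                kids.append(parse_node())
                if pos >= len(s):
                    error("unbalanced parentheses")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                error(f"unexpected character {s[pos]!r}")
        start = pos
        while pos < len(s) and s[pos] not in _LABEL_END:
            pos += 1
        name = s[start:pos].strip()
        name = name.split(":", 1)[0]  # drop branch length
        base, tag = name, None
        if "#" in name:
            base, tag = name.split("#", 1)
            if not re.fullmatch(r"H?\d+", tag):
                error(f"malformed hybrid tag {tag!r}")
        if tag is not None:
            node = hybrid_of_tag.setdefault(tag, ("h", tag))
        else:
            node = ("n", next(fresh))
        children.setdefault(node, [])
        children[node].extend(kids)
        if base and not kids:
            prev = labels.get(node)
            if prev is not None and prev != base:
                error(f"conflicting labels {prev!r}/{base!r} for hybrid #{tag}")
            labels[node] = base
        elif base and kids and tag is None:
            pass  # internal node label: ignored
        return node

    root = parse_node()
    if pos != len(s):
        error("trailing characters")

    edges = []
    for parent, kids in children.items():
        for k in kids:
            edges.append((parent, k))
    leaf_nodes = [v for v in children if not children[v]]
    for v in leaf_nodes:
        if v not in labels:
            if v[0] == "h":
                raise ENewickError(
                    f"hybrid #{v[1]} referenced but never given children or a label: {text!r}"
                )
            raise ENewickError(f"unlabelled leaf in {text!r}")
    leaf_labels = {v: labels[v] for v in leaf_nodes}
    if not edges:
        return PhyloNetwork([], leaf_labels)
    return PhyloNetwork(edges, leaf_labels)


def parse_newick_tree(text: str) -> RootedTree:
    """Parse a plain rooted Newick tree (no hybrid tags allowed)."""
    if "#" in text:
        raise ENewickError("hybrid tags are not allowed in plain Newick trees")
    n = parse_enewick(text)
    return RootedTree(n.graph.edges(), n.labels)


def write_enewick(n: PhyloNetwork) -> str:
    """Serialize a network; hybrid children are written at the first
    occurrence, later occurrences are bare ``#Hk`` references."""
    desc = n.descendant_labels()
    retics = n.reticulate_nodes()
    hyb_num = {
        v: i + 1
        for i, v in enumerate(sorted(retics, key=lambda v: (tuple(sorted(desc[v])), str(v))))
    }
    expanded = set()

    def order_key(v):
        return (tuple(sorted(desc[v])), str(v))

    def render(v):
        tag = f"#H{hyb_num[v]}" if v in hyb_num else ""
        if tag and v in expanded:
            return tag
        expanded.add(v)
        kids = sorted(n.graph.successors(v), key=order_key)
        if kids:
            return "(" + ",".join(render(k) for k in kids) + ")" + tag
        return n.labels.get(v, "") + tag

    return render(n.root) + ";"
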