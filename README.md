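# dcnet

Divide-and-conquer construction of rooted phylogenetic networks from
incompatible cluster sets, built around a catalog of canonical "simplest"
cluster sets and their precomputed networks.

## The problem

Gene trees for the same taxa frequently disagree: hybridization, horizontal
transfer and recombination produce evolutionary histories that no single
rooted tree can display.  A rooted phylogenetic network — a rooted DAG whose
leaves are bijectively labelled by the taxon set 𝒳, with *reticulate* nodes
of indegree ≥ 2 — can represent the conflicting signal.  The standard input
is the set 𝒞 of clusters (proper subsets of 𝒳) displayed by the input
trees; the goal is a network that *softwired-represents* every cluster:
for each C ∈ 𝒞 there is a switching (one retained parent per reticulate
node) in which some tree edge has descendant leaf set exactly C.  The
reticulation number ∑_{indeg(v)>0}(indeg(v) − 1) = |E| − |V| + 1 measures
how far the network is from a tree.

Cluster-based methods in the Cass/Lnetwork/BIMLR family are
divide-and-conquer (DC) algorithms: they build the incompatibility graph
IG(𝒞) (an edge joins each pair of clusters that are neither disjoint nor
nested), solve each connected component separately after collapsing its
maximal ST-sets (taxon subsets that behave like clean subtrees) into single
composite taxa, and merge the per-component subnetworks over a containment
backbone.  The resulting networks satisfy the *decomposition property*: two
clusters share an IG component iff their representing edges share a
biconnected component of the network.

The key observation this package operationalizes: after collapsing, only a
handful of *simplest* cluster sets (no ST-set left) can occur for small IG
components, up to relabeling of taxa.  Up to cluster-set isomorphism there
is exactly **one** simplest set whose IG is an incompatible pair
({{1,2},{2,3}}), a small family whose IG is a three-node path, and
**twelve** whose IG is a triangle.  Networks for these canonical sets are
solved once, frozen, and transferred to any isomorphic instance by leaf
relabeling and block expansion — no per-instance search needed.

## What the package provides

- **Cluster algebra** (`dcnet.clusters`): compatibility, incompatible taxa,
  cluster extraction from rooted trees.
- **Incompatibility graph** (`dcnet.incompat`): components and topology
  tags (pair / 3-path / triangle / other).
- **ST-set machinery** (`dcnet.simplify`): restriction 𝒞|_S, maximal
  ST-sets, Collapse to the simplest form with an invertible block map.
- **Isomorphism** (`dcnet.isomorphism`): cluster-set isomorphism after
  collapse, canonical keys for catalog lookup, network isomorphism.
- **Networks** (`dcnet.network`): rooted DAGs, switchings,
  softwired/hardwired representation checks, decomposition-property
  verification, maximal subtrees.
- **Catalog** (`dcnet.catalog`): the 17 canonical simplest sets with
  verified minimal-reticulation network fixtures, plus an exhaustive
  enumeration oracle that recomputes the class counts from first
  principles.
- **Construction** (`dcnet.construct`): the full DC pipeline —
  collapse, decompose, catalog lookup / bounded fallback search, transfer,
  decollapse, merge — with every output verified softwired.
- **IO and CLI** (`dcnet.io`, `dcnet.cli`): plain-text cluster files,
  Newick trees, extended Newick (#H hybrid tags) networks, DOT export, and
  seeded fixture generators.

## Worked example

The textbook instance 𝒞 = {{1,2}, {1,2,3}, {3,4}}.  Clusters {1,2,3} and
{3,4} overlap without nesting, so a tree cannot display both; {1,2} is the
only maximal ST-set.

```sh
$ printf '1,2\n1,2,3\n3,4\n' > example.clusters
$ dcnet simplify example.clusters
simplest: ClusterSet(universe={1+2,3,4}, clusters=[{1+2,3}, {3,4}])
block: 1+2 -> {1,2}
dropped: {1,2}
$ dcnet classify example.clusters
0	1	singleton	{1,2}
1	2	pair	{3,4} {1,2,3}
$ dcnet build --clusters example.clusters
(((1,2),(3)#H1),(#H1,4));
```

Reading the output: collapsing {1,2} into the composite taxon `1+2` leaves
{{1+2,3},{3,4}} — an incompatible pair, so it is isomorphic to the unique
pair-class representative {{1,2},{2,3}} and the catalog network is reused.
The built network has one reticulation (leaf 3 has two parents): switching
3 under its left parent displays {1,2,3} (and {1,2}), switching it right
displays {3,4}.  The cherry `(1,2)` is the decollapsed ST-set, visible as a
maximal subtree.  `dcnet check --mode softwired|decomposition` verifies any
eNewick network against a cluster file.

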