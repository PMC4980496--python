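# Methods

## Objects and conventions

A cluster is a nonempty proper subset of the taxon universe 𝒳; trivial if
a singleton.  Two clusters are compatible iff disjoint or nested; a set is
compatible iff pairwise compatible, which is exactly tree-representability.
The incompatibility graph IG(𝒞) has one node per nontrivial cluster and an
edge per incompatible pair.

An ST-set S (|S| > 1) is compatible with every cluster and has a pairwise
compatible restriction 𝒞|_S.  We exclude S = 𝒳 as a candidate (collapsing
the whole universe would destroy the instance; the source definitions are
silent).  Collapse replaces each maximal ST-set by one composite taxon; a
set with no ST-set is *simplest*.  Collapse is defined as a single
simultaneous pass (`collapse_once`); because nothing rules out a pass
creating new ST-sets, `to_simplest` iterates to a fixpoint and composes
block maps so that blocks always name original taxa.  Composite taxa are
named from their sorted blocks (`1+2`), keeping outputs diffable.

Universe conventions.  Isomorphism, canonical keys, catalog lookup and
enumeration require the universe to equal the union of the clusters —
taxa outside every cluster would create spurious isomorphism classes (an
isolated taxon changes |𝒳′| and breaks the uniqueness of the pair class).
The ST-set operations themselves tolerate isolated taxa and clusters equal
to the union, because restriction naturally produces both; with such inputs
maximal ST-sets can overlap, which raises a witnessed error instead of
silently picking one (disjointness is assumed by the collapse semantics but
holds automatically only under the union convention).  The top-level
builder accepts isolated taxa and attaches them directly under the final
root.

Restriction keeps intersections equal to the restricted universe (they are
compatible with everything, so ST-set tests are unaffected); consequently
`ClusterSet` tolerates a cluster equal to its universe.  The network
builder represents such a *spanning* cluster by the edge into the root of
the network built for the remaining clusters.

## ST-sets at scale

Exhaustive subset enumeration is exact and is used up to 11 taxa (it also
powers the overlap diagnostics).  Beyond that we use a reduction: **every
ST-set contains a two-taxon ST-set.**  If S is an ST-set, 𝒞|_S is
compatible; take the lowest internal node of its containment tree and two
leaf children x, y.  No nontrivial cluster contains exactly one of x, y
(inside S it would be a separating cluster of 𝒞|_S below that node;
outside, compatibility with S forces containment or disjointness), and
that condition is precisely "{x,y} is an ST-set".  So `is_simplest` is a
pair scan, and maximal ST-sets are computed by iterated ST-pair merging;
the two routes are cross-validated on random instances in the test suite.

## Isomorphism and canonical keys

Two cluster sets are isomorphic when, after collapsing to simplest form, a
taxon bijection carries one cluster family onto the other.  The published
definition, read literally, constrains only pairwise co-membership of
taxa; under that weak reading, sets with different cluster families (even
different IG topologies, e.g. {{1,3},{1,2,4},{1,2,3}} versus
{{1,2,4},{1,3},{2,3}}, which share the co-membership graph K₄ minus an
edge) would be identified, and the transfer construction — which relabels
a network leaf-for-leaf and must represent the target cluster-for-cluster
— would fail.  The strong (family) reading is therefore the default; the
weak check is available behind `strong=False` for fidelity experiments.

Canonical keys encode a simplest set under its minimal taxon relabeling.
Taxa are grouped by signature (the sorted sizes of the clusters containing
them); signature groups, ordered by signature, occupy consecutive canonical
positions, and the encoding is minimized over within-group permutations.
Signatures are isomorphism-invariant, so equal keys are exactly
isomorphism (cross-validated against explicit bijection search in the test
suite).  The search is exact permutation enumeration with signature
pruning — catalog universes have ≤ 7 taxa, so exactness beats
sophistication; the bound is 10 taxa, above which direct isomorphism
testing is the supported route.

## Networks and verification

Networks are rooted DAGs with a single root, no parallel edges, and leaves
bijectively labelled.  A switching keeps one incoming edge per reticulate
node; since every non-root node then has exactly one parent, the switched
graph is a spanning tree and no leaf is ever orphaned (the "unreachable
leaves" corner case is moot under this definition, and the code excludes
unreachable labels anyway).  Softwired representation enumerates
switchings — with descendant sets folded as integer bitmasks over the leaf
alphabet — up to a cap of 2¹⁶ switchings; hardwired representation reads
descendant sets off the unswitched graph.

The decomposition check quantifies existentially over witness mappings ε:
clusters in one IG component must map into one biconnected component of
the underlying undirected graph, distinct IG components into distinct
ones.  We collect up to 32 candidate witness edges per cluster and solve
the assignment as a bipartite matching between IG components and
biconnected components; if truncation could have hidden an assignment the
result is INCONCLUSIVE, distinct from a refutation.

Maximal subtrees are nodes all of whose strict descendants have indegree 1
(a reticulate node never roots one — it is entered from outside by
definition), maximal under ancestry.

## The catalog

Entries are exactly the published canonical simplest sets: one pair class,
four path classes, twelve triangle classes.  Their networks are **derived,
not copied**: the drawn figures are not textually specified, so each
fixture is found by the bounded minimal-reticulation search and frozen as
eNewick under `src/dcnet/data/` (`scripts/regenerate_catalog.py` rebuilds
them deterministically).  Any softwired-correct representative is
acceptable — transfer between isomorphic sets does not depend on which
network is stored.  `verify_catalog` re-checks every entry: simplest,
correct IG topology, leaves match, softwired representation, decomposition
property, pairwise distinct keys.  Minimality is asserted only where it is
a theorem at this scale: an incompatible set admits no tree, so the
r = 1 fixtures are minimal; higher-r fixtures are minimal within the
bounded search space that produced them, and are reported as such.

### The enumeration oracle and a discrepancy

`enumerate_simplest` enumerates, for a given IG topology, all sets of two
or three distinct proper nonempty clusters over universes of up to
`max_taxa` taxa in which every taxon occurs (the union convention; without
it class counts are unbounded), filters to the topology and to simplest
sets, and partitions by canonical key.  Clusters are bitmasks throughout;
the pair criterion above keeps the simplest filter cheap.

The oracle reproduces the published pair count (exactly one class over ≤ 4
taxa) and triangle count (exactly twelve classes over ≤ 7 taxa, matching
the printed representatives one-to-one).  For the path topology it finds
**five** classes over ≤ 6 taxa where four are published: the extra class
is {{1,4},{1,2,3},{1,2,4,5}}, confirmed simplest by independent brute
force and isomorphic to no printed set (its cluster-size multiset (2,3,4)
rules a match out immediately).  The published case analysis for the
"middle-intersection properly contains the side-intersection" case
implicitly assumes the containing side cluster adds no taxon of its own;
the missed variant is the exact analogue of published pairs that differ
only by one extra non-collapsible taxon in the other cases.  The catalog
deliberately keeps only the published entries; members of the fifth class
fall through lookup to the fallback search, so construction soundness is
unaffected.  The acceptance suite asserts the published count and is
left failing rather than adjusted.

## Construction pipeline

`build_network` strips trivial clusters (re-added as leaves), then
recursively:

1. compatible set → containment (Hasse) tree, with taxa in no cluster
   below the root;
2. otherwise collapse *globally* to simplest form.  The global collapse is
   what makes every maximal ST-set of the input a maximal subtree of the
   output: blocks of a global collapse always have compatible restrictions
   and expand to subtrees.  (Collapsing only per component provably breaks
   that property, e.g. {{1,2},{2,3},{4,5},{6,7}} has maximal ST-set
   {4,5,6,7} spanning two singleton components.);
3. decompose the collapsed set's IG into connected components (the
   decomposition property is stated for connected components; "biconnected"
   in the source is read as its name for these, since a three-node path is
   not 2-connected in standard terminology);
4. per multi-cluster component: collapse again with respect to the
   component alone, look the simplest form up in the catalog by canonical
   key (transfer = leaf relabeling through the bijection), else run the
   fallback search; decollapse component blocks, which may contain other
   components' clusters, by recursion;
5. merge over a Hasse backbone in which each component's taxon union is a
   placeholder mega-taxon, then graft subnetworks and expand the global
   blocks.

Clusters nested strictly inside a component's union are distributed into
that component's blocks; nested component unions are reached the same way.
Pairwise compatibility of the merge family (component unions plus
leftover clusters) is a consequence of the decomposition and is asserted
with witnesses rather than assumed.  Any distribution or verification
failure falls back to solving the component together with its nested
clusters as one collapsed problem; every component subnetwork and the
final network must pass softwired verification, or construction errors
out — soundness is checked, never presumed.  A runtime memo keyed by
canonical form reuses fallback solutions across isomorphic components
within a session (the catalog mechanism, extended at run time).

### Fallback search

For a simplest incompatible set the search tries taxon-removal sets R in
order of increasing size then lexicographically, requiring the restriction
to the remaining taxa to be compatible (its Hasse tree is the backbone).
Reattachment is guided by *site chains*: clusters meeting R are grouped by
their restriction base C∖R; each group is a chain of attachment nodes
stacked on the edge representing the base (clusters with smaller removed
parts lower); each removed taxon gets one parent per chain at the lowest
chain cluster containing it.  A second variant adds a parent above the
root for every removed taxon (one extra reticulation each), which lets any
taxon switch out of any cluster that must exclude it and in practice makes
every compatible-restriction removal set feasible.  Multi-parent
reticulations arise naturally (e.g. {{1,2},{1,3},{1,4}} needs a
three-parent reticulation; no two-parent single-reticulation network
represents it).  Below the best guided reticulation count, an exhaustive
pass enumerates parent placements (subdividing any current edge, or above
the root) in deterministic order under a trial budget (default 3000 per
count); within that budget the returned network has the smallest
reticulation number the search space contains.  Exceeding `max_r`
(default 3, configurable) is an explicit error, never an approximation.

## Synthetic data

Three seeded generators (byte-identical output per seed):

- *random-trees*: rooted binary trees by recursive random bipartition —
  every compatible input shape, no unary nodes;
- *expanded-catalog*: a catalog entry with each taxon replaced by a
  disjoint block of 1–3 fresh taxa (inverse collapse), with the entry as
  ground truth — the end-to-end probe of the isomorphism/transfer
  machinery;
- *random-clusters*: uniform random subsets (sizes 2 to n−1) over up to 8
  taxa, rejected until an incompatible pair exists.

The soundness suite mixes these 40/30/30 over 500 fixtures (≤ 8 taxa, ≤ 6
clusters) and checks softwired representation of every input cluster, the
reticulation identity, the maximal-ST-set/maximal-subtree property (for
incompatible inputs, where the collapse machinery is engaged), and the
decomposition property where conclusive; the builder runs with max_r = 8
there, since random 7–8-taxon sets with 5–6 overlapping clusters can need
seven reticulations.  What these fixtures do not emulate: real gene-tree
estimation error (clusters from misestimated trees), taxon sampling bias,
or instances beyond 8 taxa; passing the suite shows the machinery is sound
on its stated domain, not that reticulation counts are biologically
minimal on hard instances (the fallback is exact only within its bounded
search space).

## Numerical/engineering choices

- Determinism everywhere: clusters ordered by (size, labels); components by
  smallest member; search loops in fixed order; fixture generators fully
  seeded.  No floating point is involved anywhere.
- Switching cap 2¹⁶, witness-edge cap 32 per cluster, fallback trial budget
  3000, canonicalization bound 10 taxa, subset-enumeration bound 11 taxa —
  all overridable parameters; exceeding one is an explicit error or an
  INCONCLUSIVE status, never a silent wrong answer.
- eNewick dialect: a hybrid node's children are written at its first
  occurrence, later occurrences are bare `#Hk` references; hybrid numbers
  are assigned by sorted descendant-leaf sets, so output is stable.

## Known limitations

- The catalog covers IG components of 2–3 clusters only; larger components
  use the fallback search, whose minimality guarantee is limited to its
  removal-and-reattach space and trial budget.
- Exhaustive enumeration of simplest classes is bounded at 8 taxa.
- Softwired verification is exponential in the reticulation number (capped);
  networks with ≫ 16 reticulations are outside the intended scale.
- Cluster-set isomorphism beyond the canonicalization bound falls back to
  bijection search, which is exact but can be slow for highly symmetric
  sets with many taxa.
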