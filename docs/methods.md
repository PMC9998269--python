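# Methods

This note documents the models, conventions and numerical choices behind
`paleorder`, and what the validation suite does and does not establish.

## Reconciliation and ancestral gene content

Gene trees are mapped onto the species tree by LCA reconciliation: each
gene-tree node maps to the most recent species node containing all its leaf
species.  A node is a duplication when the leaf-species sets of its two
children intersect (species-overlap rule) or when the input carries an NHX
`D=Y` tag; tags are never downgraded.  Editing poorly supported duplication
nodes is treated as upstream preprocessing and not implemented.

An ancestral gene at species node *A* is a reconciled lineage present at
*A*.  Three mutually exclusive anchor cases are enumerated per gene tree,
in deterministic post-order (ids `<treeIndex>.<k>`):

* a speciation node mapped exactly to *A*;
* a gene-tree edge whose species path crosses *A* strictly (parent mapped
  strictly above, child strictly below);
* a child of a duplication node mapped to *A* itself, with the child mapped
  strictly below — the duplication has happened by *A*, so each emerging
  copy is a separate ancestral gene.

Losses are handled by parsimony: lineages are only asserted on paths
connecting observed descendants, so extinct side-branches create no ghost
genes.  Descendants of a lineage in species *below* the ancestor come from
the anchor's own subtree (and therefore partition the extant genes below
the ancestor).  For a species *outside* the ancestor's clade, the
orthologues are the extant genes under the nearest gene-tree ancestor of
the anchor whose subtree reaches that species — the divergence point of the
two lineages.  Minimality keeps this assignment as tight as the tree
allows; where a duplication sits between the ancestor and the outgroup, one
outgroup gene can legitimately stand for several co-orthologous ancestral
genes, and the adjacency projection treats such genes as multi-valued
markers.  Without this outgroup layer, every ingroup–outgroup comparison
would be empty and roughly a third of the adjacency signal at deep
ancestors would be lost.

## Adjacencies and linearization

Pairwise conservation is tested after projecting each genome onto the genes
with an orthologue in the comparison, so lineage-specific insertions are
transparent; adjacency itself is then strict (gap 0).  A comparison
contributes at most one vote per extremity pair, which stops tandem arrays
from inflating weights.  Edge weights therefore lie in [1, N_i].

Linearization is a greedy maximum-weight path cover: edges sorted by
(weight desc, lexicographic extremity key asc) and accepted iff both
extremities are unused and acceptance closes no cycle (union-find over
genes).  The tie-break key — (min gene id, its end, max gene id, its end) —
makes the output fully deterministic without a seed.  Greedy acceptance is
a 1/2-approximation of the optimal path cover, not an exact optimiser; on
uniform random 4-gene graphs it is suboptimal in roughly 8% of instances.
This is a property of the method itself (conflicts are resolved locally by
weight, never by global search) and is retained deliberately; on clean,
near-linear adjacency graphs the two coincide.

`constrained_2pass`: the tree parameter t (default 0.35) is interpreted as
the maximum fraction of informative species in which a gene's descendant
copy number may differ from 1 (0 and ≥ 2 both count as deviations) for the
gene to be *constrained*; `passes = 2` means the constrained-only
linearization is followed by the insertion pass.  Insertion treats the
adjacencies between consecutive constrained genes as breakable
*provisional* links: an unconstrained gene or run may open a gap and chain
itself between the two constrained neighbours, with candidate edges (full
graph, at least one unconstrained endpoint) accepted in decreasing weight
under the same degree/cycle rules.  Gaps whose insertions fail to close are
rolled back — dangling chains are detached and the original join restored —
so placed constrained genes are never reordered or split.  This reading of
the tree parameter and of the insertion order is this package's own design;
the original tool does not define them in the material available.

`multi_integration`: each CAR is contracted to a meta-marker whose tail and
head are the CAR's free terminal extremities; graph edges joining terminal
extremities of different CARs are re-aggregated and linearized by the same
greedy rule, for a configurable number of rounds (default 2).  The pass is
idempotent when no inter-CAR edge exists.

CARs are canonicalized for output: flipped so the lexicographically
smallest terminal gene sits leftmost, ordered by descending length then id.
All writers are byte-deterministic after canonicalization.

## Contiguity and accuracy metrics

L70 is the smallest number of CARs whose lengths (gene units) sum to at
least 70% of the total; G50 is the length of the CAR at which the
cumulative descending sum first reaches 50%.  Chromosomal-scale
classification uses strict inequalities: vertebrates L70 < 100 and
G50 > 450; plants L70 < 20 and G50 > 450.  The reconstruction-quality
filter used before dynamics analyses is G50 > 230 and L70 < 40.

Truth comparison operates on oriented adjacency sets (unordered extremity
pairs) in a shared gene-id space; genes private to either side are excluded
from the sets and counted separately.  Agreement is defined as the Jaccard
index TP/(TP+FP+FN), which satisfies the identity
1/(1/sensitivity + 1/precision − 1) whenever TP > 0; the identity is what
ties the three headline percentages together.

## Simulator

The simulator is the package's stated world for validation, not a fit to
any particular taxon.  A root genome of n genes (default 5,000) on c
chromosomes (default 20, sizes as equal as possible, strands uniform)
evolves along the dated tree; per branch, event counts are
Poisson(rate × branch length) per type and are applied in uniformly random
order at uniformly chosen positions:

* inversion / duplication segment lengths are geometric (mean 5 genes);
* reciprocal translocations exchange chromosome tails (degenerate cuts are
  redrawn, structurally impossible events are logged infeasible and
  skipped);
* losses remove one uniformly chosen gene; gains insert a new single-gene
  family; WGD (scheduled per branch) doubles every chromosome, then each
  duplicate pair is fractionated back to one copy with probability
  1 − retention (default retention 0.5).

Gene lineages are tracked explicitly (speciation and duplication split
points recorded), so the emitted forest is exactly congruent with the event
history, every extant gene traces to one root or gained gene, and gene
counts reconcile with the event log branch by branch.  Everything derives
from one `numpy` generator seeded by `seed`.

The benchmark configurations (`paleorder.benchmarks`) fix an 8-leaf
ultrametric tree of root age 100 My (total branch length 450 My, mean
branch 32.1 My) and rates inversion 0.45, translocation 0.10, fusion 0.035,
fission 0.035 events/My — about 20 rearrangements per branch, inversions
dominating, as in vertebrate-like gene-order evolution.  The
duplication/loss variant adds 50 expected segmental duplications (mean 5
genes ≈ 5% of families) and 250 expected losses (≈ 5% of genes) over the
tree.  These values were chosen a priori from the stated benchmark
description and are not tuned.  Benchmarks score the two oldest non-root
ancestors: the root itself has no outgroup and is systematically harder,
while shallow ancestors are nearly trivial.

What a green benchmark does *not* establish: the simulator draws breakpoint
positions uniformly (no fragile sites or hotspots), has no gene-tree
inference error (trees are exactly true), no assembly fragmentation or
missing genes, and no rate heterogeneity across lineages or genes.  Real
reconstructions face all of these; the simulation validates the
reconstruction logic, not its behaviour under noisy inputs.

## Dynamics

Successive genomes are projected onto one-to-one orthologues (multi-copy
genes are ambiguous to place and dropped).  Synteny blocks are maximal
strictly collinear runs with consistent relative orientation — a gap-0
stand-in for chained-homology detectors; gap tolerance would only change
counts on noisy real data, not on clean fixtures.  Breakpoints are counted
as half the number of block ends interior to a chromosome in at least one
of the two genomes; interior rearrangements leave an even count (inversion
and reciprocal translocation 2 each, fusion and fission 1 each), and the
rare odd counts produced by events at chromosome extremities are floored.

Interchromosomal events are called per the ≥ 20-gene group rule on
chromosomes larger than 200 genes (the floor applies to the source
chromosome of each view).  Candidate links from the fission view (one
parent chromosome, several child groups) and the fusion view (one child
chromosome, several parent groups) are grouped into connected components of
the link graph: one event per component, classified translocation when both
views contribute, so a reciprocal exchange counts once.  Components holding
several interacting events are undercounted; under spaced events the counts
match the simulator's log exactly.  Rates are counts divided by branch
length (My); branches shorter than 5 My are flagged as small-sample.
Breakpoint maps accumulate counts in non-overlapping windows of fixed gene
count on a reference genome.

## Degenerate inputs and determinism

Multifurcating species trees, duplicate labels, non-dense ranks, duplicate
genes and empty tables are rejected with located errors; missing branch
lengths default to 0 My with a warning (rates then refuse to divide).
Reconstruction runs write a manifest with input hashes, version and seed;
identical config and inputs give byte-identical outputs, which the test
suite asserts.
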