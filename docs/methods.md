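# Methods

`orthopath` reconstructs ancestral gene orders on a fixed unrooted binary
phylogeny from pairwise synteny-block homologies.  The method has two
stages: construction of paralogy-free multi-genome orthology sets from the
pooled pairwise homologies, and greedy reconstruction of ancestral genomes
minimizing the total double-cut-and-join (DCJ) distance over the branches
of the tree.  This note records the model, the algorithmic and numerical
choices, and what the simulation-based validation does and does not show.

## Genomes and the DCJ distance

A genome is a set of linear chromosomes (or assembly fragments, which are
treated exactly like chromosomes); each chromosome is an ordered sequence
of signed genes.  For two genomes on the same n genes, every gene
contributes a tail and a head extremity; consecutive genes define
adjacencies, and chromosome ends are capped (T1 for the first genome, T2
for the second).  Blue edges are the adjacencies of genome 1, red edges
those of genome 2.  After closing capped paths — a T1–T1 path is closed by
a red edge, a T2–T2 path by a blue edge, a mixed path by collapsing its
caps — every vertex has one blue and one red edge and the graph decomposes
into κ alternating cycles.  The distance is d = n′ − κ with n′ the number
of blue edges, which after closure equals n + χ₁ + (number of T2–T2
closures).  The T2–T2 term matters: without it, fissions that genome 2
needs relative to genome 1 are not counted (e.g. (1 2) vs (1)(2) would
come out at distance 0).

The test oracle for this formula is deliberately independent: genomes are
represented as bare adjacency sets and a bidirectional breadth-first
search applies every possible DCJ rewiring, including ones that pass
through circular intermediates (which the formula implicitly allows, and
which are required for transposition-like differences to cost 2).  The
formula agrees with the search exhaustively over all genomes on up to 3
genes and on hundreds of seeded random pairs with up to 7 genes.

**Fragment correction.**  When one or both genomes are fragmented
assemblies, part of the DCJ score is an artifact: fusions or fissions
that merely equalize chromosome counts.  In the capped graph each
artifactual operation appears as a same-genome cap closure, so we subtract
|#T1–T1 − #T2–T2| from the raw distance, clamped at zero.  When both
genomes have same-genome closures in equal number (a genuine exchange of
content between chromosomes), the correction vanishes, which is the
desired behaviour.  This is a surrogate for the published correction the
score refers to; it is exact on pure-fragmentation cases.

## Orthology sets (greedy paralogy resolution)

Pairwise homologies from synteny blocks (minimum block size is the one
knob, applied at graph construction) are pooled into a homology graph on
genes.  Orthology is transitive, so each connected component should be one
orthology set with at most one gene per genome — two per WGD descendant.
Components violating that bound are resolved by deleting reported edges
one at a time until every component complies.

Each deletion maximizes F = Σ_v c(v), where c(v) counts the genomes
represented in the star of v (v plus its neighbours) in the remaining
graph, a WGD descendant contributing up to two.  On a paralogy-free union
of cliques F equals the sum of squared component sizes — the "total edges
in the transitive closure" objective — which is why the greedy prefers
splitting one small piece off a large component over halving it.  Ties are
broken by minimizing the residual paralogy F⁺ = Σ_v (ν(v) − c(v))
evaluated on the closure (component-wise), then by preferring the
candidate with the larger closure objective, then by the smallest edge
key.  The stopping condition is evaluated on the closure: a component
whose *closure* would place two same-genome genes in one set is still
conflicted even if every raw star looks compliant (e.g. the path
x₁–y–z–x₂ with x₁, x₂ from one genome).

Evaluating F on the raw stars rather than on the closure is a deliberate
reading of an ambiguous prescription: on the closure, deleting any edge
that does not disconnect a component leaves the score unchanged, which
reduces the greedy to blind lexicographic shaving; on raw stars a single
spurious bridge between two families costs nothing to delete while every
true intra-family edge costs 2, so noise edges are removed first.  On
simulated six-genome data with 5% spurious/missing homologies, ≥95% of
true families are recovered intact and every output set is paralogy-free
(the latter is a hard invariant enforced at output).

Oversized components ("tangles", threshold 100 genes, the size components
essentially never exceed in practice) are first split by repeatedly
extracting the highest-degree gene together with its immediate homologs.
Two-gene components whose genomes are separated by three or more ancestral
nodes are dropped up front: no ancestor would receive such a gene anyway.
Singleton leftovers carry no order information and are discarded.

## Ancestral gene content

Presence of each orthology set is a binary character on the unrooted tree.
Ancestral states minimize gain+loss events (small parsimony, computed by a
Sankoff up/down pass rooted at the topological center); any
minimum-change labelling satisfies the majority fixed point — a gene is
present in an ancestor exactly when present in at least two of its three
neighbours — because flipping a state against a strict 2-of-3 majority
always removes one more mismatch than it creates.  Ties during the
traceback resolve toward presence, and because the traceback starts at the
tree's center this pushes gains as central ("early") as possible without
committing to a root.  Verified over seeded random trees: the majority
rule is a no-op on the output, and adding a gene to one more leaf never
removes it from an ancestor.

A WGD descendant's doubled ancestor is not part of the binary tree; for
content purposes it carries every gene with at least one surviving copy in
the descendant.

## Reconstruction (pathgroups greedy)

An ancestral genome is a growing set of red adjacency edges shared by the
breakpoint graphs of all branches at that node.  A pathgroup bundles the
partial paths starting at one ancestral extremity, one per incident
branch.  Fragments (maximal red-connected runs) partition the ancestral
genes at all times; a red edge joining the two ends of one fragment would
create a circular chromosome and is never allowed.

**Priorities.**  Moves are ranked by immediate gain, then by a one-step
look-ahead (the best gain any pathgroup affected by the move could achieve
next), then by a deterministic vertex key; a lazy priority queue with
local updates keeps the whole construction near-linear in gene count.
The immediate gain of adding red edge {x, y} in one branch is
telomere-aware:

* +1 if x and y are the two ends of one path (an alternating cycle
  closes);
* −1 if the two paths being joined both already end at a leaf cap (a path
  with a leaf cap at either end always becomes a cycle at final capping,
  and the join forfeits one of the two);
* 0 otherwise (ancestor-telomere-pair paths are cancelled by their closure
  edge and count nothing either way).

Moves with negative total gain are simply not made — leaving both
extremities as ancestral telomeres is at least as good.  This end-type
accounting is what the refined priority tables of the production
implementations encode; with naive cycle counting the solver matched the
exhaustive median optimum on 86/100 small seeded instances, with
telomere-aware gains on 100/100, with no change to the two-rule ladder.

**Unequal gene content.**  Each branch's breakpoint graph is restricted to
the genes shared by the ancestor and that neighbour.  Skipping a
neighbour's genes that the ancestor lacks merges their flanking
adjacencies — precisely the "hidden cycle" extension through runs of
absent genes, applied once at graph construction (the walk itself is
exposed as `hidden_cycle_search` and unit-tested against the graph
construction).  Red edges whose gene is missing from a neighbour are left
out of that branch's graph, so a pathgroup may hold three, two or fewer
paths.  Reported branch lengths are exact DCJ distances between the
induced sub-genomes on shared content.

**Median and small phylogeny.**  The median of three genomes runs the
greedy over three branches on the majority gene content.  The small
phylogeny solver first builds ancestors progressively from the leaves
inward, then sweeps over ancestral nodes re-solving each as a median of
its current neighbours; a new median is accepted when its adjacent branch
lengths sum to **no more than** the current ones (the ≤ rule lets plateau
moves escape local minima), and sweeps stop when the total stops
decreasing, so sweep totals are monotonically non-increasing.  On
six-leaf trees with 1000 genes and 0.12 operations per gene per branch —
the density regime where the greedy is known to be accurate — the
reconstructed total tree length is within ~2% of the generating operation
count (the check allows 5%), at a few seconds per replicate.

**WGD descendants.**  A descendant T of a whole-genome duplication is
attached through a doubled ancestor A spliced into its branch.  A is built
from the genes present exactly twice in T: each of its red edges is
realized twice in the T-branch (once per copy), and the copy pairing of
each edge is chosen to maximize cycles.  The T–A branch length is the
distance between T and A-as-doubled-genome under the same greedy pairing —
an upper bound on the exact double distance that matches brute-force
enumeration over copy labelings on all two-gene cases we can enumerate,
and is 0 for a perfectly doubled unrearranged descendant.  After
convergence, each maximal run of single-copy genes in T is re-inserted
into both halves of A next to the matching extremity of a flanking
duplicated gene (left flank preferred; orientation follows the flank's
sign in A, so insertion does not change the DCJ distance).  When both
copies of a flank carry runs at the same extremity the runs are
consolidated, copy-1 run first; only membership and flank placement are
contractual, since the internal order of a consolidated run is largely
arbitrary.  Because that arbitrariness inflates the A–R branch (R being
A's ancestral neighbour) by roughly one rearrangement per added
breakpoint, a crude correction of s/3 per single-copy run of length s > 3
is subtracted from that branch; runs of up to 3 genes are left
uncorrected.

**Block validation.**  For any pairwise block table and a reconstructed
ancestor on the path between the two genomes, `block_integrity` reports
per block the number of consecutive block gene pairs no longer adjacent
among the block's genes in the ancestor (a split across fragments counts
as a break) and the mean absolute rank shift of the block's genes between
block order and ancestor order, taking the better of the two orientations
so an intact but reversed block scores zero.

## Synthetic data

The generator evolves a root genome (identity gene order split over a
configurable number of chromosomes) down the tree, rooted for simulation
at the topological center.  Defaults are the study conditions used
throughout the validation: 6 leaves, n = 1000 genes, 5 chromosomes, and
d/n = 0.12 operations per gene per branch.  The operation mix is
inversion 0.8 / translocation 0.15 / fusion 0.025 / fission 0.025:
inversions dominate real plant gene-order evolution, and a mix this
inversion-heavy keeps the true distance essentially equal to the drawn
operation count at low density, so the generating count is a meaningful
reconstruction target (a uniform mix lets fusions and fissions cancel,
and is available via `op_weights`).  Transpositions are excluded by
default because DCJ counts them as two operations.

WGD branches apply half of the branch's operations, double the genome,
apply the rest, then fractionate: each event deletes a geometric-length
run (mean 2.5, matching the observation that fractionation removes two or
three consecutive paralogs at a time, with adjacent deletions merging
into longer runs) from one homeolog, never removing a family's last copy,
until half of the families are single-copy.  Optional per-branch gene
loss produces unequal content.  Homology tables are emitted from the true
families, grouped into colinear blocks; noise q drops each true pair with
probability q/2 and adds round(q/2 · n_true) spurious pairs between random
genes, each in its own single-pair block, as random matches would appear.

What passing simulations do **not** show: real synteny-pipeline output has
block-level correlated errors, tandem-duplicate ambiguity and
annotation-dependent gene-family structure that uniform random noise does
not mimic; real genomes violate the uniform-rate, inversion-dominated
operation model; and fractionation in the simulator is spatially uniform,
unlike the biased fractionation seen after real WGDs.  Results on
simulated data certify the algorithms under their own model assumptions,
not field accuracy.

## Numerical and degenerate-input conventions

* All tie-breaking is deterministic (sorted keys); identical inputs and
  seeds reproduce byte-identical pipeline reports (wall-clock timings are
  written to a separate file).
* Chromosome identity is orientation-free: a chromosome equals its
  reverse complement, and genomes are unordered sets of chromosomes.
* Circular chromosomes are rejected on input and never created during
  reconstruction; the brute-force test oracle may pass through circular
  intermediates because the distance model prices them.
* Empty genomes have distance 0 to each other; writing an empty genome is
  an error; an ancestor with empty assigned content is represented by an
  empty gene order.
* Small-instance quality checks enumerate all genomes on up to 5 genes
  (a few thousand after canonicalization) and all vertex partitions of
  components with up to 8 genes; those sizes are where exhaustive search
  is exact and fast, and the greedy's scaling behaviour is checked
  separately at n = 1000.
* The fractionation correction may make corrected branch lengths
  fractional; raw integer DCJ lengths are always reported alongside.

## Known limitations

* The look-ahead is one step deep over affected pathgroups; the refined
  multi-hundred-entry priority tables of the production lineage are not
  reproduced, and some of their accuracy at higher d/n with them.
* Unfinished paths at termination mean reconstructed ancestors come out
  as fragments rather than full chromosomes; the fragment correction
  compensates in the reported lengths but fragment joining itself is not
  optimized further.
* The doubled-ancestor construction requires exactly two copies in the
  descendant (single-copy genes are handled by re-insertion afterwards);
  descendants of two stacked WGDs are out of scope.
* The greedy orthology resolution is exact only on small components; on
  dense, heavily conflicted components (far outside the sparse-noise
  regime) it can land measurably below the exhaustive optimum, though
  never above it, and its output is always paralogy-free.
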