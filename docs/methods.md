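# Methods

## The pipeline and its assumptions

phyloshoot assumes the hard phylogenetic work — clustering proteins into
homolog groups, aligning them, inferring and rooting their gene trees —
has been done once, ahead of time, by an upstream orthology workflow. At
search time it only has to decide *which* pre-computed tree a query
belongs to and *where* on that tree it attaches. Consequences of this
design: search accuracy is bounded by the quality of the input trees; the
database is static between rebuilds; and a query with no homologs in the
database is reported as such rather than forced into a tree.

## Database construction

**Tree splitting.** Placement cost grows with tree size, so families
larger than `max_subtree_size` (default 2500 genes) are partitioned by a
greedy root-to-tip traversal: at every node whose clade exceeds the limit,
recursion descends into the children; each maximal clade at or under the
limit becomes one subtree. A singleton leaf stranded at a split node is
merged into the smallest sibling subtree created at that node when the
merged size still fits, else it forms its own subtree. Each subtree's
member set is therefore a clade, or a clade plus sibling singletons —
always connected in the source tree, which makes the supertree (the
source tree with each member set contracted to a leaf, contracted-edge
branch lengths retained) well defined. Supports on surviving supertree
nodes are kept.

**Outgroups.** Each subtree records the non-member gene with the smallest
branch-length path to the member clade root (ties: lexicographically
smallest id). A close outgroup keeps the subtree alignment compact and
the post-placement rooting stable. Since every such path passes through
the clade's stem edge, the choice is independent of where along the path
the measurement starts.

**Representative profiles.** For a (sub)tree of N member genes,
k = min(N, max(⌈N/10⌉, min(20, N))) representatives are chosen: rows of
the member sub-MSA are encoded one-hot over (column × residue) — 21
symbols, the 20 amino acids plus X, gaps as the all-zero block — so
squared Euclidean distance counts column disagreements; k-means
(scikit-learn, 10 restarts, seed derived from the build seed and the
family/subtree id) clusters the rows and each cluster contributes its
closest-to-centroid member (ties: lexicographic id). Should a cluster
come back empty, the farthest-from-its-own-centroid unselected row is
promoted until k representatives exist. With N ≤ 20 every gene is a
representative and no clustering runs.

## Search

**Scoring.** The builtin engine computes Smith–Waterman local alignments
(BLOSUM62, gap open 11, extend 1, via Biopython's C aligner) and converts
raw score S to a bit score S′ = (λS − ln K)/ln 2 using the standard
gapped-BLOSUM62 Karlin–Altschul constants λ = 0.267, K = 0.041, and to an
e-value E = m·n·2^(−S′) with m the query length and n the total residue
count of the profile set. The default pass requires a shared exact 4-mer
between query and representative before aligning — a stand-in for a
seeded first pass; the sensitive retry (triggered automatically when the
first pass assigns nothing) aligns every representative.

**Tree assignment.** Hits above the e-value cutoff (10⁻³) are dropped.
The best remaining hit fixes the primary candidate tree; every other
tree whose own best hit has e-value < best·10¹⁰ is kept as an additional
candidate (per-tree best hits are compared, not all hits). When the best
e-value underflows to zero, the smallest positive double is used as the
base of the ratio. Candidates are capped at 5 trees to bound placement
cost; the cap lives in `SearchConfig` and can be raised.

**Query-to-MSA alignment.** The query is aligned to the candidate's
alignment columns against a per-column residue-frequency profile (expected
BLOSUM62 score per column; rows with a gap in the column dilute the
profile), global with affine gaps 11/1. Reference columns are never
modified: query-only insertion states are consumed and discarded
(keep-length), and terminal unmatched reference columns are free so a
fragment query is not penalised for the flanks it does not cover.

**Placement.** Every edge of the reference tree is scanned: attaching the
query mid-edge, the tree's Fitch parsimony cost is computed over the
parsimony-informative columns of the extended alignment (≥ 2 distinct
residues each seen ≥ 2 times; gaps and X are missing data, i.e. the full
state set; polytomies fold children sequentially). Costs are computed
incrementally — per-node state sets and cumulative costs are built once
post-order, and per edge only the path back to the root is recomputed —
so the scan is exact yet O(n·depth·L). Ties are broken by topological
proximity to the best-hit representative's leaf, then the smallest
descendant leaf label, then the smaller clade, making placement fully
deterministic. The query's pendant branch length is its normalized
p-distance to the nearest reference leaf; existing branch lengths are
split at the attachment midpoint and otherwise untouched; the new node
carries no support value.

**Rooting and grafting.** In a split family the query is placed in the
subtree *with* its outgroup present; the result is rerooted on the
outgroup's pendant edge (supports move with their bipartitions), the
outgroup removed and the degree-2 node suppressed with branch lengths
summed. The supertree's subtree-id leaves are then replaced by the member
trees (the queried one by the placed tree), restoring the contracted edge
lengths on the boundary edges, so the caller receives the complete family
tree with the query embedded.

## Orthology

Species overlap: post-order, each node's species set is the union of its
children's; a node is a duplication iff any two children's sets intersect
(for polytomies, any pair). Orthologs of the query are the leaves whose
LCA with it is a speciation node. Genes from the query's own species are
always paralogs under this rule (inparalogs are not distinguished). No
species tree is consulted, so incomplete lineage sorting or hidden
duplications (a duplication where loss removed all overlap) are labelled
as speciations — the known failure mode of the method.

## The simulator

The generator emulates the builder's inputs end to end with a single seed
driving all randomness: a Yule species tree on `n_species` tips rescaled
so every root-to-tip path equals `tree_height` (expected substitutions per
site); gene lineages walking down it with duplication rate δ and loss
rate μ per unit branch length (families with < 2 surviving genes are
rejected and redrawn); sequences evolving by at most one substitution per
site per branch — substitution probability 1 − e^(−b), replacement uniform
over the other 19 residues. There are **no indels**, so the true alignment
is the raw sequences and placement/orthology accuracy is measured without
alignment inference as a confounder; real databases do not have this
luxury, so passing benchmarks here bound what alignment noise would
erode, they do not measure it. Support values are assigned uniformly
(default 100), so the benchmark's support filters are structural rather
than statistical in simulated data. Defaults — 12 species, height 0.5,
δ = 0.3, μ = 0, 50 families, 300 columns — give moderately diverged,
duplication-bearing, loss-free families whose true ortholog pairs are
exactly the non-duplication LCA pairs of the generating process; μ > 0 is
available for robustness studies but hides duplications from the
species-overlap rule by construction.

Closed forms used by the test oracles: for two leaves at branch lengths
b₁, b₂ from their ancestor, P(identical site) = e^(−(b₁+b₂)) +
(1 − e^(−b₁))(1 − e^(−b₂))/19; for small δ the expected duplication count
per family is ≈ δ × (total species-tree branch length), exact up to
second-order compounding.

## Numerical and design choices

- N/10 rounds up, so k ≥ 1 always.
- The splitting algorithm, outgroup rule, MSA encoding, k-means restart
  and empty-cluster policies, end-gap treatment, pendant-length rule and
  all tie-breaks were open design points; the choices above were made for
  determinism and clade preservation and are recorded in the build
  parameter record so databases are reproducible byte-for-byte.
- Robinson–Foulds distances are computed on unrooted views, symmetric
  difference of non-trivial bipartitions over 2(n−3), requiring identical
  leaf sets and n ≥ 4.
- Precision@k is set-overlap of the top-k predicted vs top-k expected
  rankings (ties in expected rankings broken lexicographically), averaged
  over cases for MAP@k; k is capped at the number of available genes.
- The leave-one-out harness prunes the query from sequences, MSA row,
  tree (splicing its parent) and representative set, re-selecting
  representatives from the pruned sub-MSA, before searching.

## Problem sizes

The bundled benchmarks run at desk scale: the study fixture is 50
families on 12 species with 300-column sequences (≈ 650 genes); the
splitting check simulates a single family of ~2600–5000 genes at 60
columns; the split-vs-unsplit comparison forces splitting with a
10-gene limit on duplication-rich ~60-gene families. These sizes keep a
full run in minutes on one core while still exercising every code path,
including supertree grafting and the sensitive retry.

## Known limitations

- The builtin engine is exact Smith–Waterman over representatives; it is
  not a speed substitute for a production aligner on large databases, and
  its 4-mer pre-filter is cruder than a real seeded search. Adapters for
  external engines/aligners/placers are deliberately out of the tested
  path.
- Parsimony placement ignores branch lengths and rate heterogeneity; on
  very short internal edges (fewer than a handful of expected
  substitutions at the alignment length) the optimal edge is genuinely
  ambiguous and placement may differ from the source topology.
- Bootstrap supports are consumed, never recomputed; the placed node has
  no support.
- Gene ids must be unique across the whole database; colliding query ids
  are prefixed with `query_`.
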