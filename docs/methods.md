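# Methods

## Candidate calling

A proteome entry is called a family candidate when three conditions hold
simultaneously:

* **length > 200 aa** (strict). The conserved ATPase region averages
  ~400 aa, so anything at or below 200 aa is treated as a peptide
  fragment. Seed-set curation for profile construction uses the
  complementary phrasing — sequences *smaller than* 200 aa are excluded,
  i.e. a 200 aa protein is a valid seed but not a valid candidate. Both
  boundaries are carried literally and independently in `ScanConfig` and
  `curate_seed_set` because the two filters serve different purposes
  (fragment removal vs. seed hygiene) and their published phrasings
  differ.
* **domain architecture**: at least one SNF2_N and at least one
  Helicase_C match, each with E-value strictly below 10⁻³. Any
  qualifying hit satisfies presence; multiple hits per domain are kept
  as evidence.
* **profile score**: the ATPase-region profile bitscore is ≥ 200
  (inclusive). Profile scoring itself (HMM build and search) is an
  external-engine concern; the package consumes a per-protein bitscore
  table and implements every decision around it. A protein missing from
  the score table scores 0 (logged), so it cannot pass.

The ATPase span defaults to the union of the best SNF2_N and best
Helicase_C hit intervals ("best" = lowest E-value, ties by bitscore then
start) because search engines do not always report a single envelope.
Extraction adds 30 aa flanks on both sides, clamped to the protein
bounds, to absorb domain-boundary inaccuracy before alignment.

Family counts are per locus: isoforms collapse to the longest protein
per `gene_id`, ties broken lexicographically by id so the choice is
deterministic. Description-keyword matching in seed curation is
case-insensitive substring matching, since public proteome descriptions
vary freely in case.

## Locus recall

Hits of family proteins against a genome are clustered by single linkage
with a genomic distance cutoff of 15 kb. The distance between two hits
is the **interval gap** gap(a,b) = max(0, max(start) − min(end) − 1):
overlapping or abutting hits have gap 0 and always co-cluster, and two
hits merge when gap ≤ cutoff. A midpoint-distance metric is available
behind `gap_metric="midpoint"` for comparison, since published
descriptions of such cutoffs rarely state the convention; interval gap is
the default because it makes overlap trivially transitive. Hits on
different target sequences never co-cluster, and strand is ignored by
default (the downstream gene predictor resolves structure), with a
strand-aware mode behind a flag.

Because hits sorted by start on one sequence connect exactly when the
next start exceeds the running maximum end by more than the cutoff,
single linkage reduces to a linear sweep; the test suite checks this
against an O(n²) pairwise union-find on random hit sets, including gaps
at exactly cutoff ± 1.

Cluster spans, padded and clamped to ≥ 1, are emitted as GFF3 `region`
records for an external gene predictor. Recalled clusters are
partitioned against an annotation by ≥ 1 bp overlap (any strand) with
annotated family genes.

## Subfamily classification and the census matrix

Reference leaves (genes with known subfamily, e.g. a fully annotated
model-species set) anchor label transfer: an unlabeled leaf takes the
label of the smallest enclosing clade that contains a reference, provided
all references in that clade agree. Disagreement yields
"not classified" — deliberately conservative, so genuinely novel members
stay unassigned rather than being voted into the nearest subfamily (a
majority-vote mode exists but is off by default).

Assignment needs a rooted tree. A tree whose root already bifurcates is
taken as rooted; a trifurcating (unrooted) tree is midpoint-rooted by
default (unit branch lengths are assumed when none are given), with an
outgroup override. Event counts and assignments can depend on rooting;
this is documented behavior, not hidden.

The census matrix counts classified members per species × subfamily over
the included whole-genome species only. Per-subfamily mean is
total / n_genomes and sd is the population standard deviation (÷ n), so
genomes lacking a subfamily contribute zeros; per-cell deviation is
(count − mean)/sd with 0 where sd = 0. Quartiles of per-species totals
use linear interpolation on the sorted values (the conventional default;
configurable).

## Reconciliation

Plain LCA parsimony: M(g) is the species-tree LCA of the species under
gene node g; g is a duplication iff M(g) = M(c) for some child c; losses
per edge are depth(M(child)) − depth(M(parent)) − 1, plus 1 when the
parent is a duplication whose child image moved. No event costs,
branch-support thresholds or rearrangement are applied — the parsimony
map is unique and fully testable, and it reproduces the
ancient-duplication-plus-mutual-loss scenarios that matter for family
histories. In-paralog groups are the maximal single-species clades with
≥ 2 leaves; relative to a species pair, two same-species genes are
in-paralogs iff their gene-tree LCA maps strictly below the pair's
divergence node.

The test oracle enumerates *every* valid gene-node → species-node map on
small trees, scores each by the same event rules, and takes the
parsimony minimum; the implementation must agree exactly on all gene-tree
shapes with ≤ 5 leaves over a 3-species tree.

## Disorder scoring

FoldIndex: score = 2.785·⟨H⟩ − |⟨R⟩| − 1.151 per sliding window, with
⟨H⟩ the mean Kyte–Doolittle hydropathy rescaled to [0, 1] via
(kd + 4.5)/9 and ⟨R⟩ the mean net charge (D,E = −1; K,R = +1; H = 0 at
neutral pH; unknown residues: neutral hydropathy 0.5, charge 0, logged).
Window default 51 (odd required); sequences shorter than the window get
one whole-sequence score. Positions scoring strictly below −0.2 are
disordered; a score of exactly −0.2 is ordered. Maximal sub-cutoff runs
shorter than `min_region_len` (default 30) are suppressed as noise.
Window and minimum region length are declared defaults, not fitted
values.

## Expression classes

FPKM ≤ 5 low, 5 < FPKM ≤ 200 moderate, > 200 high; both boundaries land
in the lower class. The classes partition [0, ∞) and are monotone in
FPKM. The per-gene "expressed" flag — FPKM ≥ 1 in ≥ 1 library by
default — is this package's operationalization of a presence call; both
parameters are exposed in `ExpressionConfig` because no numeric
definition of "expressed" is standard. A confidence-interval–based
cutoff variant is deliberately not implemented (no reproducible
procedure to implement).

## Synthetic data: what it emulates and what it does not

The generators produce inputs whose *decision-relevant* structure matches
real data while everything else is simplified:

* Proteomes are uniform random residues; domain matches are emitted
  directly as table rows with E-values and scores in realistic ranges
  (E ∈ [10⁻³⁰, 10⁻⁵], profile scores 250–600 for planted members). Each
  decoy violates exactly one calling rule, so filter failures localize.
  Passing tests therefore demonstrate the correctness of the calling
  logic, not the sensitivity of any search engine on real sequences.
* Genome hits tile 2 kb locus blocks separated by specified gaps, so the
  expected cluster count under any cutoff follows from the gap list by
  direct comparison. Real tblastn hit scatter (chained HSPs, repeats,
  pseudogenes) is not modeled.
* Planted tree histories are constructed to be *provably* recoverable by
  LCA parsimony: each duplication grafts a sister copy of an event-free
  gene-tree leaf (+1 duplication, 0 losses), and each loss prunes a
  species leaf whose sibling subtree keeps survivors and never empties a
  root-side subtree (+1 loss). Placements violating these constraints
  are rejected rather than silently planted, because parsimony provably
  undercounts them (e.g. losing both species of a cherry). Real
  histories can of course be non-parsimonious; the generator makes no
  claim there.
* FPKM values are drawn uniformly inside the planned class interval
  (high capped at 2000); no count noise or library-size variation is
  modeled.

All generators take a mandatory seed and use a single private RNG
stream; identical specs give byte-identical files.

## Problem sizes and numerics

The test and acceptance workloads use deliberately small sizes chosen to
exercise every code path: proteomes of tens of proteins, hit sets up to
n = 200 (500 random sets for the clustering oracle), exhaustive
reconciliation enumeration up to 5-leaf gene trees over 3 species, 50
planted tree histories on a 6-species tree, and a 44-locus recall replay
(23 annotated + 21 novel). These sizes already make the brute-force
oracles non-trivial while keeping the whole suite in seconds.

Tie-breaks and degenerate inputs are fixed deterministically throughout:
lexicographic id tie-breaks in isoform collapse, sorted output orders,
z = 0 where sd = 0, single whole-sequence disorder score for
shorter-than-window proteins, and empty inputs yield empty outputs
rather than errors wherever an empty census is meaningful.

## Known limitations

* No live profile-HMM search, aligner, tree estimator or gene predictor
  is invoked; those are adapter boundaries by design, and their outputs
  are consumed as tables/newick.
* Midpoint rooting of unrooted gene trees can change reconciliation
  event counts and clade anchoring relative to the (unknown) true root.
* The census quartile method and the disorder window/region-length
  defaults are conventions, exposed in config rather than inferred.
* In-paralog calls inherit any error in the input gene-tree topology;
  no support-value filtering is applied.
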