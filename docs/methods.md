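# Methods

## Occurrence model

The raw material is a binary document × concept occurrence record: a
concept either appears in a document or it does not. Term frequencies,
positions and sections are ignored. This is the simplest model under which
document-level co-occurrence statistics are well defined, and it is all the
downstream association weights consume. The corpus total T is the number of
documents, including any documents carrying no concept occurrence that the
caller declares explicitly.

## Association weights and genetic concept profiles

A concept's genetic concept profile (GCP) assigns one weight per gene-class
thesaurus concept, computed from the 2×2 document co-occurrence table
(a = both, b = concept only, c = gene only, d = neither; T = a+b+c+d).
Three weights are implemented:

* **uncertainty** (default): the symmetric uncertainty coefficient
  U = 2·I(X;Y) / (H(X)+H(Y)), with mutual information and entropies in
  nats and 0·log 0 ≡ 0. U is clamped to 0 when the observed co-occurrence
  rate a/T does not exceed the independence expectation (a+b)(a+c)/T², so
  only positive association contributes. U is bounded in [0, 1], symmetric
  in the two concepts, and equals 1 exactly for perfect co-occurrence
  (b = c = 0, 0 < a < T).
* **pmi**: positive pointwise mutual information,
  max(0, log[(a/T) / ((a+b)/T · (a+c)/T)]).
* **raw**: the co-occurrence count a.

All weights are 0 when a = 0. The uncertainty default was chosen because a
bounded, symmetric coefficient matches the "strength of association"
semantics of concept profiling without favouring rare or common genes the
way raw counts or unbounded PMI do. A concept's association with itself is
trivially perfect and carries no information, so a concept contributes no
weight to its own profile.

Profiles are L2-normalised before any inner product. Without
normalisation, inner products would be dominated by corpus prevalence and
cohesion scores would not be comparable across groups; with it, all
matching scores of non-negative unit vectors lie in [0, 1] and a score of 1
means identical profiles. A profile with no positively associated gene is
*degenerate*: it is flagged, excluded from clustering and from the
permutation universe, and reported in the run log.

Concept names are mapped to thesaurus ids by case-insensitive exact match
against canonical names and synonyms; a name matching more than one entry
is ambiguous and excluded from profile building (mirroring the removal of
a disease term that could not be mapped uniquely). No fuzzy matching is
attempted, so the ambiguity semantics are reproducible.

## Cohesion score and permutation test

The cohesion of a group of m ≥ 2 profiles is the mean inner product over
all C(m, 2) pairs; with unit-norm rows it is computed stably as
(|Σᵢwᵢ|² − m) / (m(m−1)). Gene g's contribution is the mean over pairs of
wᵢ(g)·wⱼ(g), expressed as a percentage of the cohesion score; the
percentages are non-negative and sum to 100 whenever the score is
positive (contributions are undefined at zero cohesion).

The permutation P-value draws `iterations` (default 200) uniform random
subsets of the same size from a comparison universe of profiles, without
replacement within a draw, and reports the fraction whose cohesion reaches
the observed score. Conventions, each of which was a genuinely open design
choice:

* P = r/n rather than (r+1)/(n+1), so P-values are exact multiples of
  1/iterations (published values at 200 iterations are multiples of
  1/200, e.g. 0.02, 0.03).
* Draws come from the full comparison universe and may overlap the
  observed group; no exclusion is stated or implemented.
* The universe defaults to the profiles of **all** corpus concepts in the
  thesaurus (diseases and genes alike), i.e. a random group is a random
  set of concepts from the literature, not a random set of the studied
  diseases. This matches the interpretation of "a random group of the
  same size" drawn from the concept space of the profiling engine, and it
  gives the test resolution: with only the 7 studied diseases as the
  universe there are 21 possible pairs, so the third-best planted pair
  could never reach P ≤ 0.05. A `permutation_universe="concepts"` switch
  restricts draws to the clustered concepts for sensitivity analysis.
* When the tested group is the entire universe (the root of the merge
  tree under the restricted universe), the only same-size draw is the
  group itself and P is exactly 1; this case is short-circuited.

All randomness flows through a single integer seed (default 17) feeding a
`numpy` Generator that is shared across the merge-tree groups in fit
order, so a fitted model is bit-reproducible.

## Clustering and projection

Profiles are compared by d = 1 − inner product, which is 0 iff two
unit-norm non-negative profiles are identical and bounded by 1 for
disjoint support. Agglomerative clustering (scipy) uses average linkage
(UPGMA) by default — no linkage is prescribed by the method description —
with complete and single available. Concepts are pre-sorted
lexicographically so that tied merges resolve deterministically. Cohesion
and P are reported for every internal node of the merge tree, in merge
order. The dendrogram exports to Newick with branch lengths spanning merge
heights (leaves sit at depth equal to the root height).

The planar projection is classical (Torgerson) metric scaling: double-
centre the squared distance matrix, take the top-2 eigencoordinates. The
eigenvalue spectrum is kept for diagnostics (negative eigenvalues flag
non-Euclidean distances) and a raw stress value is reported. Coordinates
are defined only up to rigid motion and reflection. A rank-0 configuration
(all concepts equivalent) projects every point to the origin with a
warning.

## Network stage

Edge lists are SIF-like TSV records (proteinA, proteinB, semicolon-
separated reference ids, source label). Symbols are uppercased; records
with swapped endpoints are merged with reference union; self-loops are
dropped with a warning.

The reference filter treats any reference supporting more than
`max_links_per_reference` (default 4) merged edges as a high-throughput
artifact: the reference is invalidated everywhere and an edge survives iff
it retains at least one valid reference. There is no minimum-reference
filter. The keep-if-any-valid-reference rule is an interpretation (the
alternative — dropping any edge that ever carried an invalid reference —
would discard well-supported edges for guilt by association); the filter
is idempotent because removing edges only lowers reference support.

The background is the simple undirected graph on the surviving edges with
N = |edges|. Seeds are looked up by symbol; seeds absent from the
background are reported, not fatal (at least 2 must be present). With the
default maximum path length 2, subnetwork nodes are the seeds plus every
non-seed node adjacent to ≥ 2 *distinct* seeds — the only way a length-2
seed-to-seed path can pass through a non-seed node; longer chains are
excluded by construction. K is the edge count of the subgraph induced on
those nodes. Whether intermediate–intermediate edges belong in K is not
decidable from the published counts alone; they are included by default
(induced-subgraph semantics) and a flag excludes them.

Each intermediate is scored with the one-sample binomial proportion
statistic z = (k/n − p₀)/√(p₀(1−p₀)/n) against p₀ = K/N, where n is the
node's **background** degree and k its distinct-seed adjacency count.
This formula is a reconstruction validated against the shipped 20-row
published benchmark: it reproduces every printed z within ±0.005 (max
deviation 0.00094), yields exactly 19 of 20 significant at the strict
cutoff z > 2.5 with FYN (z ≈ 2.457) the sole failure, and preserves the
printed descending order. Pooled two-sample variants of the proportion
test do not reproduce the table and were rejected. Background degree (not
subnetwork degree) is the only reading consistent with printed link counts
(116, 153) that far exceed any plausible subnetwork degree. Significance
is strict (z > 2.5): no printed value equals the cutoff, and the one
non-significant published node lies just below it. The benchmark fixture
stores period-decimal floats; the loader also accepts the comma-decimal
dialect the source table was typeset in.

## Synthetic data

`simulate_corpus` emulates a MedLine-like corpus: each document mentions
exactly one disease (round-robin over diseases, so shares are equal), and
gene mentions are independent Bernoulli draws — genes in a planted pair's
shared pool at `p_comention_shared` in that pair's documents, everything
else at `p_comention_background`. Defaults: 7 diseases, 3 planted disjoint
pairs, 500 genes, 20,000 documents, shared rate 0.05, background rate
0.005, pool size 20 genes per pair, seed 17. The pool size is the one
free parameter with no published analogue; 20 genes per pair gives each
cluster a gene support comparable to the ~20-row contribution tables of
the original analysis. These sizes run the full pipeline in well under a
minute per seed on one CPU while leaving the planted signal statistically
comfortable rather than trivial: profile weights concentrate on pool
genes because only they exceed the independence clamp systematically.

What the generator does **not** emulate: MedLine's highly skewed concept
marginals, multi-disease documents, synonym noise in entity recognition,
and correlated gene mentions beyond the shared pools. Passing tests
therefore demonstrate that the pipeline recovers planted co-mention
structure under an idealised null, not that it would recover the published
disease clusters from real literature — those require the original corpus
and thesaurus and are explicitly out of scope.

`simulate_network` emits an Erdős–Rényi background (p = 0.02 over 150
proteins minus the planted nodes) in which every edge carries a unique
reference, plus planted intermediates wired to `links_per_intermediate`
(default 4) random seeds with no other links — so their (n, k) and hence
their z are known exactly — plus hub references each supporting 10 edges
with no other support, which the 4-link cap must purge entirely. Ground
truth (planted wiring, purge list) is returned and written as a YAML
sidecar. Both generators are bit-reproducible per seed.

## Problem sizes and tolerances

The test suite exercises scaled-down corpora (2,100 documents, 100 genes)
for unit tests and the full default spec (20,000 documents, 20 generator
seeds) for the planted-pair recovery check; the whole suite runs in well
under a minute. Numerical oracles are held to 1e-9 (brute-force cohesion
and contributions, naive linkage heights) or 1e-8 (Procrustes recovery of
planar configurations, principal-coordinates cross-check); Monte-Carlo
estimates are held to 3 standard errors of their exact enumeration
values; the published z benchmark is held to its printed precision
(±0.005).

## Known limitations

* The uncertainty-coefficient weight is this package's documented choice,
  not a reconstruction of any proprietary profiling engine's internals;
  `pmi` and `raw` are provided for sensitivity analysis.
* Degenerate (all-zero) profiles are excluded rather than imputed.
* The permutation test draws with replacement *across* iterations, so P
  has Monte-Carlo noise of order √(P/iterations); exact enumeration is
  only used in tests.
* `max_path_length` supports 1 and 2; longer paths would change the
  intermediate definition qualitatively and are not implemented.
* No multiple-testing correction is applied across the merge-tree groups
  (none is applied in the source methodology).
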