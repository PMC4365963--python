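# Methods

`crossherd` implements a meta-analytic pipeline for finding gene modules that
are co-expressed *consistently across several expression datasets* measured
on the same phenotype groups — the motivating setting is liver expression in
several pig populations split into low- and high-androstenone (LA/HA) groups,
with one RNA-seq population and two microarray populations per group.

## Preprocessing

Count matrices are moved onto the intensity scale with log2 counts-per-million
(prior count 0.5 added to each count, twice the prior added to each library
size). This is a deliberate simplification of precision-weighted
mean–variance modelling: the only downstream consumer of the transformed
matrix is the Pearson correlation of per-gene profiles, which uses no
precision weights, so the weights would be discarded anyway.

Probe-level microarray matrices are collapsed to one row per gene by keeping
the mapped probe with the largest between-sample variance (unbiased n−1
denominator; ties keep the lexicographically smallest probe id). All
matrices are then restricted to their sorted common gene set, and regrouped
into an LA set and an HA set. Each set needs at least two datasets for the
joint meta-analysis to be meaningful; a singleton set is allowed only by
explicit override.

## Cross-dataset edge weights

Within each dataset of a phenotype set, the Pearson correlation r is computed
for all n(n−1)/2 unordered gene pairs, and each pair receives a *rank ratio*:
its average-tie rank among all pairs ordered by |r| (ascending; rank 1 =
smallest |r|), divided by the pair count. Absolute values are used for the
ranking because with tens of millions of pairs the signed ranking would award
high ratios even to vanishingly small positive correlations.

For a pair with sorted rank ratios r(1) ≤ … ≤ r(n) over the n datasets, the
edge weight is the joint cumulative probability

P(r₁,…,r_n) = n! ∫₀^{r(1)} ∫_{s₁}^{r(2)} … ∫_{s_{n−1}}^{r(n)} ds_n … ds₁,

the probability that the i-th smallest of n independent uniforms is ≤ r(i)
for every i. The inner limits chain through the integration variables
s₁,…,s_{n−1}; this is the only reading under which the expression is the
joint CDF of uniform order statistics, and the implementation follows it.
The integral is evaluated exactly by iterated polynomial integration from the
innermost variable outward, carrying coefficients in the next integration
variable (supported for n ≤ 10; the tests cross-check it against Monte-Carlo
simulation and literal symbolic integration).

Before network construction, a pair is retained only if its *signed*
correlation is strictly greater than +0.50 in **every** dataset of the
phenotype set. This removes weak pairs and pairs with conflicting
directionality in one step. The retained pairs form a weighted undirected
graph whose edges carry the per-dataset correlations and the joint-CDF
weight. Correlation of the pair blocks is computed in gene-index blocks so
the ~29.5-million-pair scale of a ~7,700-gene universe stays within memory;
results are independent of the block size.

## Consensus clustering and cluster statistics

Each network is partitioned by Infomap — the two-level map-equation
heuristic, delegated to igraph's implementation with an explicitly seeded
RNG so that every run is reproducible. Because single runs are
seed-dependent, partitions are stabilised by iterative consensus clustering:
`runs_per_iter` seeded runs (seeds `master_seed + i`, counting across
iterations; default 500, reducible for small problems) are reduced to a
node-pair co-assignment frequency matrix, frequencies below `tau` (default
0.5) are zeroed, and the thresholded matrix is re-clustered as a weighted
graph until all runs of an iteration agree exactly. The iteration count is
surfaced; exceeding `max_iter` (default 10) raises with the last agreement
fraction.

The cited significance methodology for map-equation clusters is
under-specified in the literature we follow, so this package fixes a
concrete, testable procedure with the same null-model semantics:

* **Node inclusion.** For member v with degree k_v and k_in within-cluster
  neighbours, the configuration-model probability that k_v endpoint stubs
  drawn from the network's remaining 2m − k_v stubs place ≥ k_in on the
  cluster's stubs is a hypergeometric tail; members with tail > `alpha_node`
  (default 0.05) are dropped, and the pass is repeated once. Note the test
  is conservative by construction when a cluster spans most of a (small)
  network — the tail then approaches 1 and valid members can be pruned; at
  study scale clusters are small fractions of the network and this does not
  arise.
* **Cluster significance.** The observed internal edge-weight sum is
  compared with the same score in `n_null` degree-preserving edge rewirings
  of the whole network (double-edge swaps; the multiset of edge weights is
  randomly reassigned to the rewired edges), giving
  p = (1 + #{null ≥ observed}) / (n_null + 1). The add-one correction
  forbids p = 0; n_null < 99 is rejected as too coarse.

Clusters with fewer than 10 members **or** p ≥ 0.05 are excluded — the
disjunctive reading: failing either criterion excludes. Each retained
cluster is summarised by the per-dataset mean ± sd of its member-pair
correlations.

## Enrichment

Every term is tested by the one-sided Fisher exact test (hypergeometric
tail) for over-representation of cluster genes. GO testing is restricted to
the biological-process namespace and offers `classic` (independent tests)
and `elim` (default): terms are processed deepest-DAG-level first (ties by
ascending term id), and when a term is significant at `elim_alpha` (default
0.01) its annotated cluster genes are removed from all ancestors before
those are tested — decorrelating parent–child tests. Annotations must be
true-path propagated; the loaders and the fixture generator do this.
Pathway catalogues are tested flat. Reported results satisfy raw p < 0.05
with ≥ 5 annotated cluster genes; deliberately, no multiple-testing
correction is layered on top of that filter. The default background is the
common-gene universe (not only network nodes), configurable.

## Cluster similarity

*Physical* similarity between an LA and an HA cluster is the hypergeometric
upper tail of their gene overlap in the common-gene universe (within-
phenotype pairs are skipped: a partition's clusters are disjoint).
*Functional* similarity between GO-enriched clusters — including
within-phenotype pairs — is the Wang graph-based semantic similarity of
their enriched term sets (edge weights 0.8 for is_a, 0.6 for part_of; the
S-value of an ancestor is the best product of edge weights along a path from
the term, memoised per term) combined by the best-match average. Its
significance is empirical: N draws (default 10,000) of two random term sets
— sizes drawn uniformly from the observed enriched-set sizes, terms sampled
without replacement from the annotation pool — give
p = #{sim_RAND > sim_CLUS}/N, strict inequality so ties favour
significance; p < 0.05 is significant. Under its own null this p-value is
approximately uniform (verified by KS test in the suite).

## Synthetic data

The generator emulates the study layout: per dataset and phenotype group, a
genes × samples matrix with planted modules driven by a shared per-sample
latent factor z ~ N(0,1).

* Intensity platform: value = baseline + sd·(√ρ·z + √(1−ρ)·ε), so two module
  genes have correlation exactly ρ in expectation. Baselines are N(8, 1),
  noise sd defaults to 1 (log-intensity scale).
* Count platform: negative-binomial counts (dispersion α = 0.1) with natural
  log mean b + β·z, β = √(v·ρ/(1−ρ)) where v = α + e^{−b} is the
  delta-method variance of the log count at the baseline mean (b ~
  N(log 200, 0.7)). After the log-CPM transform the within-module
  correlation lands near ρ; the calibration assumes module genes are a small
  fraction of the library (in very small panels CPM normalisation absorbs
  part of the shared factor and attenuates the correlation — the 20-seed
  calibration run with a 300-gene background measured means 0.87/0.90
  against a 0.9 target for counts/intensities).
* Phenotype-specific modules simply omit the latent factor in the other
  group's samples.
* Each dataset consumes its own RNG stream spawned from the master seed, so
  adding datasets never changes earlier ones; all outputs are reproducible
  from the seed.

The reference design (`example_design`) is 3 datasets (one count, two
intensity) × 2 phenotype groups, 300 genes, three 30-gene modules at
ρ = 0.85, 20 samples per group — optionally with the third module planted
only in LA to emulate a phenotype-specific signature cluster. What passing
tests on these data show is that the pipeline recovers block-latent
correlation structure planted under its own distributional assumptions; real
expression data add library-composition effects, batch structure, outlier
samples and correlated background that the generator deliberately does not
model, so recovery rates here are upper bounds, not forecasts.

The ontology fixture is a random rooted DAG (is_a/part_of edges, bounded
depth) with one term annotating exactly a designated gene set — a planted
positive for enrichment — and true-path-propagated random annotations for
the rest.

## Numerical and design choices

* Rank ties receive average ranks; probe-collapse variance ties keep the
  smallest probe id; elim processes ties in ascending term id — all
  deterministic.
* Retention is strict (> +0.50), matching trimming of pairs ≤ +0.50; the
  cluster filter keeps p < 0.05 (not ≤) and size ≥ 10.
* Empty retained-pair sets produce an empty network and a clean exit, not an
  error.
* Problem sizes in the test suite and acceptance script (300-gene designs,
  100 consensus runs per iteration, 199-graph rewiring nulls, 10⁶-draw
  Monte-Carlo oracles) are scaled-down choices that keep the full suite
  fast while leaving every statistical check well-powered; the package
  defaults (500 runs, 999 nulls, 10,000 similarity draws) match the
  intended analysis scale.

## Known limitations

* The two-level map equation only; no hierarchical or overlapping variants.
* The node-inclusion and rewiring nulls are this package's concrete
  instantiation of "compare to a degree-preserving null"; other published
  instantiations will differ in detail.
* Fisher/hypergeometric testing inherits database-version sensitivity for
  real GO/KEGG catalogues; nothing here pins a release.
* The empirical functional-similarity p has resolution 1/N and is biased
  low when enriched term sets are tiny.
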