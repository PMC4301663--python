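# Methods

## The generative model

Evolution proceeds over a fixed, shared set of τ time periods (the edges
of a known species history; topology is irrelevant once per-edge lengths
are extracted, so periods are treated as exchangeable). Gene *i* has a
constant intrinsic rate r<sub>i</sub>; pacemaker *k* has per-period paces
β<sub>k,j</sub> ~ N(0, σ<sub>P</sub>²); gene-specific error factors are
α<sub>i,j</sub> ~ N(0, σ<sub>G</sub>²), all independent. The observed
branch length is ℓ<sub>i,j</sub> = t<sub>j</sub> r<sub>i</sub>
e^{α<sub>i,j</sub>} e^{β<sub>PM(i),j</sub>}. The simulator materialises
exactly this identity (the returned factors reproduce the table bit-wise)
and assigns genes to pacemakers in contiguous equal blocks; when k does
not divide n, the first n mod k parts take one extra gene. A single seed
feeds five independent sub-streams (rates, periods, paces, errors,
dropout), so changing one law leaves the other draws untouched.

In log space,

log ℓ<sub>i,j</sub> = log t<sub>j</sub> + log r<sub>i</sub> + α<sub>i,j</sub> + β<sub>PM(i),j</sub>,

so two genes of the same pacemaker share both the period term and the pace
term, while genes of different pacemakers share only the period term. The
shared log t<sub>j</sub> component means between-pacemaker correlations
are positive, not zero; identifiability rests on the *contrast* between
within- and between-pacemaker correlation, which is governed by
σ<sub>G</sub>/σ<sub>P</sub>.

## Parameter defaults and why

| parameter | default | rationale |
|---|---|---|
| n, τ | 100, 25 | the simulation study's standard problem size |
| pair dropout | 2/3 | emulates the low pairwise MAST agreement of real prokaryote tree sets (≈1/3 of pairs usable) |
| r<sub>i</sub> law | log-uniform on [0.5, 2] | a 4-fold rate spread; only ratios matter after the log transform, so any strictly positive law is equivalent up to intercept shifts |
| t<sub>j</sub> law | uniform on [0.1, 1] | strictly positive period durations of the same order; the law is config-exposed |
| σ<sub>P</sub> | 0.4 | a moderate pace dispersion (±50% rate swings per period); the swept quantity in all experiments is the ratio σ<sub>G</sub>/σ<sub>P</sub>, with σ<sub>G</sub> = ratio·σ<sub>P</sub> |
| δ<sub>r</sub> | 0 (simulation) | dropout already sparsifies; admits every non-negative correlation. Raise for tree collections |
| min_periods | 3 | minimum shared observations for a pair fit (tree mode instead uses the ≥10-leaf MAST filter) |

## Pairwise inference

Both coordinates of a log-length pair carry the same error variance, so
ordinary least squares (which assumes an error-free x) would bias the fit
by the arbitrary choice of which gene is "x". The errors-in-both-variables
(Deming) model with the slope fixed at one leaves a single free parameter,
and its maximum-likelihood value is the mean offset b̂ = ȳ − x̄ — also the
minimizer of the orthogonal sum of squares at slope one (tests verify this
against a 1-D numerical minimizer). e^{b̂} estimates the rate ratio. The
correlation is the plain sample Pearson coefficient of the log lengths;
pairs with a constant vector (undefined correlation) or too few shared
observations are skipped with a logged reason.

## Graph completion

The correlation graph keeps pairs with r ≥ δ<sub>r</sub>, weighted by r
with derived distance 1 − r, and analysis proceeds on the giant connected
component. Classical MDS needs a complete matrix, so missing cells are
completed by the most reliable connection: among paths with the fewest
hops, the minimal *product* of edge distances. The implementation runs one
BFS plus a layer-by-layer dynamic program per source (O(n·m) total) and is
tested cell-by-cell against exhaustive simple-path enumeration on small
graphs. Because products of sub-unit distances shrink with path length,
multi-hop completions are optimistic (small); this is harmless here
because the completion only seeds the initial embedding — the iterative
MDS stage re-fits to the original partial matrix. A sum-of-distances
objective is available as a config switch for users who prefer a metric
completion.

## Embedding

Classical (Torgerson) MDS double-centers the squared completed distances
and keeps every eigenvector with a positive eigenvalue — the maximal
dimension determined by the data — unless `n_dims` caps it (30 is the
customary cap for large real collections). Kruskal's non-metric MDS then
iterates from that configuration: disparities are fitted by isotonic
regression of configuration distances on the observed dissimilarities
(ties pooled), and the configuration takes a gradient step on stress-1
with a backtracking line search that only ever accepts a stress decrease,
so the stress sequence is non-increasing by construction. Unobserved
(dropped) pairs contribute nothing to the stress. Defaults: tol 1e-4 on
the relative stress change, 300 iterations, 1e-8 jitter if two embedded
points coincide (the isotonic step needs distinct distances).
Non-convergence returns the current embedding with a flag rather than
raising.

## Cluster number selection

k-means (k-means++ seeding, best of 25 restarts, deterministic given
seed) minimizes within-cluster scatter. The dispersion reported and used
by the gap statistic is W<sub>K</sub> = Σ<sub>r</sub> D<sub>r</sub>/(2
n<sub>r</sub>) with D<sub>r</sub> the sum of squared pairwise distances
over unordered member pairs — equal to half the k-means inertia. (The
classical definition sums ordered pairs; the two differ by a constant
factor 2 that cancels in every gap difference, so the selected k is
unaffected. A raw, unnormalized pairwise-distance variant is exposed via
flags.) Reference datasets are uniform over the axis-aligned bounding box
of the embedded points, B = 50 by default, re-used across k; reference
k-means runs use 10 restarts, which keeps the scan fast with no
measurable effect on selection. The chosen k is the smallest with
deltaGap[k] = Gap[k] − Gap[k+1] + sigma[k+1] ≥ 0, with sigma the
reference standard deviation inflated by √(1+1/B); when no k in the
scanned range qualifies, the result is flagged as None and clustering
falls back to the smallest scanned k.

## Partition distance

Reconstruction quality is the minimum number of genes to recolor under
the best bijection between estimated and true parts (empty parts pad the
smaller side). The exact optimum comes from a maximum-weight assignment
on the part-intersection matrix. The greedy matcher repeatedly takes the
heaviest remaining intersection edge (ties broken lexicographically, then
leftover parts paired in ascending index order); it guarantees at least
half the optimal similarity on any input and is exactly optimal whenever
every source part keeps a strict majority of its members in a single
target part — since then every off-diagonal edge is lighter than both of
its diagonal neighbours, the diagonal matching is optimal and is the one
greedy constructs. Both facts are exercised by randomized tests against
the assignment solver, and the exact solver itself is validated against
brute-force enumeration of all color bijections on small instances.

The stay-or-uniform baseline (each gene keeps its part with probability α,
else re-draws uniformly among all k parts, its own included) has expected
identity similarity (k−1)αn/k + n/k; at α = 0 the normalized partition
distance of a random reconstruction concentrates near 1 − 1/k, which is
the saturation level the accuracy sweep approaches at high noise.

## Tree mode

Gene trees over overlapping taxon sets are compared on their maximum
agreement subtree. Trees are treated as rooted at a designated shared
taxon (default: the lexicographically smallest shared leaf); the rooted
MAST is computed by the classical dynamic program over node pairs, using
a maximum-weight assignment over children at internal/internal pairs, so
multifurcations are handled exactly. Tie-breaks among equally large
agreement sets are deterministic (the child-matching case is preferred,
then descent into the first tree); only the cardinality and the
agreement property are contractual, and tests assert exactly that against
a brute-force subset oracle. Restriction to the agreement set removes
unused edges and contracts degree-2 nodes while summing path lengths; the
two edges incident to the root are one unrooted split and are merged into
a single summed entry, so aligned vectors have one entry per unrooted
edge and no structural zeros. Pairs whose agreement set is smaller than
`min_leaves` (default 10) are discarded; the surviving aligned vectors
enter the same Deming machinery as simulated tables.

The simulator can render each gene as a Newick caterpillar over
(τ+3)/2 taxa whose 2m−3 unrooted edges carry the gene's τ branch lengths
(odd τ only). All genes share the topology, so MAST keeps every leaf and
tree mode reproduces table-mode pair fits exactly — the equivalence test
of the two input paths.

## What the synthetic benchmark does and does not show

The generator reproduces the statistical structure the method assumes:
lognormal multiplicative noise, a shared period process, equal-size
pacemaker blocks, and pair-level dropout that is independent of the data.
Real collections differ in ways the benchmark does not emulate: dropout
there is driven by MAST size, hence correlated with phylogenetic
discordance (HGT, incomplete lineage sorting); branch lengths are
estimates with reconstruction and alignment error rather than draws from
the model; pacemaker blocks need not be equal-sized, and rate laws are
unknown. Passing the synthetic suite therefore demonstrates correctness
of the machinery and its behavior under the model, not performance
guarantees on real data.

## Problem sizes used in the shipped experiments

The accuracy sweep runs k ∈ {2, 4}, ratios {0.25, 0.5, 1, 2, 4}, 10
replicates each at n = 100, τ = 25, 2/3 dropout; the gap-selection
experiment runs 20 end-to-end replicates at ratio 0.5 with a k-scan over
1..10; the acceptance script uses 4 replicates per ratio and 10
gap-selection runs. These sizes give Monte-Carlo standard errors small
enough for the qualitative claims (monotone degradation, saturation at
1 − 1/k, k = 2 selection) while keeping a full run to minutes on one CPU.

## Known limitations

- The method clusters only the giant component; genes thresholded out of
  it are reported but not labelled.
- The gap statistic's uniform-box reference is used in the embedding's
  full dimensionality; in very high dimensions the reference becomes
  conservative, which biases selection toward small k (harmless for the
  two-pacemaker regime studied, but worth revisiting for large k).
- Unrooted MAST is approximated by the rooted computation at a fixed
  outgroup; an exhaustive re-rooting search would be quadratic and is not
  implemented.
- Non-metric MDS is a local optimizer; the classical-MDS initialisation
  makes it reproducible, but a globally lower-stress configuration may
  exist. Tests check it is competitive with a random-restart search on
  small instances.
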