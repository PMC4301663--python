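# pmpi — pacemaker partition identification from gene branch lengths

Under the universal-pacemaker view of genome evolution, genes do not evolve
at independent clock-like rates: whole groups of genes accelerate and
decelerate together, following a shared latent "pacemaker". `pmpi`
implements the multiple-pacemaker generalisation — each gene follows
exactly one of *k* pacemakers — and answers the inverse question: given the
branch lengths of many gene trees, which genes share a pacemaker?

It is aimed at molecular-evolution researchers who have a collection of
gene trees with branch lengths (or want to study the method on simulated
data) and want to recover the latent partition of genes into pacemakers
and decide how many pacemakers the data support.

## The model and the method

Gene *i* with intrinsic rate *r<sub>i</sub>*, following pacemaker
*PM(i)*, has observed branch length on tree edge (time period) *j* of
duration *t<sub>j</sub>*:

    ℓ_ij = t_j · r_i · e^{α_ij} · e^{β_{PM(i),j}},
    α_ij ~ N(0, σ_G²),   β_kj ~ N(0, σ_P²)

Genes sharing a pacemaker see the same β sequence, so their log branch
lengths are correlated; the ratio σ_G/σ_P controls how identifiable the
partition is. The pipeline:

1. **Slope-one Deming regression** per gene pair in log space. The log
   transform makes the noise additive and homoscedastic, and both
   coordinates carry the same error variance, so the trend line has slope 1
   and the maximum-likelihood intercept is b̂ = ȳ − x̄ (the rate ratio is
   e^{b̂}). The pair's Pearson correlation *r* of log lengths measures
   pacemaker affinity; 1 − *r* is the working distance.
2. **Gene correlation graph**: an edge for every pair with *r* ≥ δ_r;
   restricted to its giant connected component.
3. **Min-hop-min-weight completion**: missing cells are filled with the
   minimal product of edge distances along a minimum-hop path, giving the
   full matrix classical MDS needs.
4. **Embedding**: classical MDS of the completed matrix initialises
   Kruskal's non-metric MDS, which re-fits the configuration to the rank
   order of the *original, partial* distances (stress-1, isotonic
   regression, observed pairs only).
5. **Clustering**: k-means on the embedding. When *k* is unknown, the gap
   statistic compares log within-cluster dispersion W_K against uniform
   reference data and picks the smallest *k* with
   deltaGap[k] = Gap[k] − Gap[k+1] + sigma[k+1] ≥ 0.
6. **Scoring** (when truth is known): partition distance — the minimum
   number of genes to recolor under the best bijection between cluster
   labels — via an exact assignment solver and via the greedy
   heaviest-edge matcher (½-approximate in general, provably exact when
   every part keeps a strict majority).

For real tree collections, branch lengths of a gene pair are compared on
their **maximum agreement subtree** (MAST): contracted edges keep their
summed path lengths, and only pairs whose MAST has at least `min_leaves`
(default 10) leaves are used.

## Worked example

```python
import pmpi

params = pmpi.ModelParams(n=60, k=3, tau=25, sigma_g=0.2, sigma_p=0.4, seed=42)
model = pmpi.PacemakerPartitionModel.from_simulation(params)
res = model.fit(k=3, seed=0)
print(res.summary())
print(res.partition_distance())
```

prints

```
Pacemaker Partition Identification
==================================================
genes (graph / giant)              60 / 60
pair fits (skipped)                598 (0)
edges >= delta_r=0                 598
embedding dims                     30
final stress-1                     0.000004
k (clusters)                       3
W_K (within dispersion)            2.5191
--------------------------------------------------
cluster sizes: 0: 21, 1: 18, 2: 21
{'n': 60, 'greedy_distance': 3, 'exact_distance': 3, 'greedy_normalized': 0.05, 'exact_normalized': 0.05}
```

60 genes in 3 true pacemaker blocks of 20 were simulated at noise ratio
σ_G/σ_P = 0.5 with two thirds of the gene pairs discarded; 598 pairs
survived dropout and were fitted. The embedding reproduces the observed
distance ranks almost perfectly (stress ≈ 0), and the recovered 3-way
clustering misplaces 3 of 60 genes (normalized partition distance 0.05) —
both matchers agree on the optimal label correspondence.

The same object works on trees: `PacemakerPartitionModel.from_trees(
"trees/", min_leaves=10)` runs MAST extraction first, and
`fit(k_range=range(1, 11))` replaces the known *k* with a gap-statistic
scan (`res.gap.table`, `res.chosen_k`).

A CLI mirrors the library: `pmpi simulate`, `pmpi trees`, `pmpi sweep`
(accuracy vs σ_G/σ_P curves), `pmpi partdist` (compare two partition TSV
files).

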