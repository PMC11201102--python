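# mmagc — meta-analytic multi-omics gene clustering

Gene-clustering algorithms group correlated genes to suggest shared
regulation and candidate pathways, but most operate on a single omics type
from a single study. `mmagc` implements MMAGC, a meta-analytic pipeline
that combines **multiple omics types** (e.g. RNA expression and DNA
methylation) from **multiple independent studies** into one gene-to-gene
correlation matrix and clusters it with a modified weighted correlation
network analysis (WGCNA) stage. Intended users are statisticians and
computational biologists who have per-study genes-by-samples matrices for
several omics platforms and want joint gene modules without pooling raw
samples across studies.

## Method

Three sequential steps:

1. **Per-study correlation.** Gene g in study k is an `S_k x V` profile
   (samples by omics). Two genes are scored by one of
   - *CC*: first canonical correlation of the two profiles, in [0, 1];
   - *MOC*: max-magnitude signed Pearson correlation over all V×V omics
     pairs;
   - *MSOC*: as MOC, restricted to matching omics types.
2. **Fixed-effects pooling.** With `r_k` the vector of the
   `p* = G(G−1)/2` pair correlations of study k, the model
   `r_k = ρ + e_k`, `e_k ~ N(0, T_k)` is fit by generalized least squares,

   ρ̂ = (Σₖ T_k⁻¹)⁻¹ (Σₖ T_k⁻¹ r_k),

   where T_k is the large-sample (Olkin–Siotani) covariance of sample
   correlations with diagonal `Var(r_ab) = (1 − r_ab²)² / S_k`. The
   *diagonal* variant (recommended) keeps only the diagonal, i.e. an
   entrywise inverse-variance weighted mean; the *full* variant assembles
   the whole `p* × p*` matrix per study.
3. **Modified WGCNA.** `a = |ρ̂|^m` (adjacency), topological overlap
   `TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)`, average-linkage
   hierarchical clustering on `1 − TOM`, minimum-cluster-size pruning. The
   soft-threshold power m is chosen at the first inflection of the mean
   connectivity change rate, which stays far below the power selected by
   the traditional ≥60 % scale-free-fit criterion and preserves network
   information.

A simulation module generates multi-study data with planted clusters
(block multivariate-normal correlation structure with within-gene,
within-cluster and between-cluster levels τ1–τ5 and a perturbed-cluster
proportion p), and an evaluation harness scores recovered partitions by
the adjusted Rand index (ARI). See `docs/methods.md` for assumptions,
parameter defaults and numerical choices.

## Worked example

```python
from mmagc.simulation import case_configs, simulate_meta
from mmagc.gene_correlation import correlation_matrix
from mmagc.meta_combination import combine_diagonal, finalize_for_clustering
from mmagc.evaluation import adjusted_rand_index, cluster_correlation_matrix

# five iid studies: 50 genes in 10 planted clusters, 3 omics, 100 samples
studies = simulate_meta(case_configs(case=1), master_seed=7)

vecs = [correlation_matrix(s.study, "MSOC") for s in studies]
pooled = combine_diagonal(vecs)
corr = finalize_for_clustering(pooled)
clusters = cluster_correlation_matrix(corr, power="inflection",
                                      min_cluster_size=3,
                                      gene_ids=pooled.gene_ids)

print("clusters found:", clusters.n_clusters)
print("ARI vs planted truth:",
      adjusted_rand_index(studies[0].labels, clusters.labels))
```

prints

```
clusters found: 10
ARI vs planted truth: 1.0
```

i.e. the pooled maximum-same-omics correlations of five studies recover
all ten planted clusters exactly (ARI 1 means the partitions agree up to
relabelling).

The same pipeline is available from the shell: `mmagc simulate` writes
per-study TSVs, `mmagc correlate` / `mmagc meta` / `mmagc cluster` run the
three steps on TSV matrices, `mmagc pipeline` chains them from one YAML
config, and `mmagc evaluate` replicates a simulation scenario into a
mean ± SD ARI table. All subcommands accept `--seed`; see `mmagc --help`.

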