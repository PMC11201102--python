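# Methods

## Overview

`mmagc` clusters genes from multi-omics data collected in several independent
studies. The pipeline has three sequential steps:

1. **Per-study gene-to-gene correlation.** Each gene g in study k is
   summarised by its `Sk x V` profile (Sk samples, V omics types). The
   association of two genes is one of:
   - **CC** — the first canonical correlation between the two profiles'
     column spaces, in [0, 1];
   - **MOC** — the signed Pearson correlation of largest magnitude among all
     `V x V` omics-column pairs;
   - **MSOC** — as MOC but restricted to matching omics types.
   All three reduce to the Pearson correlation (its absolute value for CC)
   at V = 1, and `CC >= |MOC| >= |MSOC|` holds pairwise because each later
   measure optimises over a subset of the earlier one's feasible set.
2. **Fixed-effects pooling.** The `p* = G(G-1)/2` distinct pair correlations
   of study k form a vector `r_k` modelled as `r_k = rho + e_k`,
   `e_k ~ N(0, T_k)`. The GLS estimate is
   `rho_hat = (sum T_k^-1)^-1 (sum T_k^-1 r_k)`. `T_k` entries use the
   classical large-sample covariance of sample correlations (Olkin–Siotani),
   whose diagonal is `(1 - r^2)^2 / Sk`. The **diagonal** variant keeps only
   the diagonal, reducing GLS to an entrywise inverse-variance weighted
   mean; the **full** variant assembles the whole `p* x p*` matrix per study.
3. **Modified WGCNA.** The pooled matrix (absolute values, clipped to
   [0, 1]) is raised elementwise to an integer power m (adjacency),
   converted to the topological overlap measure (TOM), and clustered by
   average-linkage hierarchical clustering on `1 - TOM`, followed by
   minimum-cluster-size pruning.

## Numerical and design choices

### Canonical correlation

Computed from the covariance blocks of the stacked omics columns via
whitened SVD: `sigma_1 = ||L1^-1 S12 L2^-T||_2` with `L` the Cholesky
factors of the within-gene blocks. A ridge `1e-8 * trace/V` on each within
block keeps collinear omics profiles solvable; on well-conditioned inputs
the result matches the unridged generalized eigenproblem to better than
1e-6. Because CCA is invariant to per-column scaling, the matrix-level path
uses correlation blocks rather than covariance blocks; the two agree to the
ridge tolerance.

### Pooling

Signed MOC/MSOC values are pooled and the absolute value is applied *after*
pooling (`pool_absolute=True` switches to pooling `|r_k|`). Pooling signed
estimates avoids folding noise around zero into a positive bias before
averaging. Correlations are pooled on the raw scale (no Fisher z), following
the fixed-effects model stated on `r_k` directly; weights clip `|r|` at
`1 - 1e-6` so a simulated perfect correlation cannot carry infinite weight.
The full `T_k` is an asymptotic plug-in estimate and can be indefinite at
finite samples; it is repaired by the minimal diagonal shift that lifts its
smallest eigenvalue to 1e-8 before factorisation, and all solves use
Cholesky factorisation rather than explicit inversion. Memory for the full
variant grows as `p*^2` per study, so it refuses inputs above 200 genes
unless the guard is raised.

### Power selection

The mean connectivity `k(m)` (average summed adjacency to all other genes)
is evaluated on the integer grid m = 1..20.

- **Traditional rule**: the smallest power with scale-free fit (adjusted R²
  of the log–log regression of binned connectivity frequency on
  connectivity, 10 equal-width bins) at least 0.60 while the relative
  connectivity drop `(k(m-1) - k(m)) / k(m-1)` is at most 1/3; if no power
  qualifies, the best-fit power is used with a warning. In practice this
  rule drifts to very high powers on pooled matrices, leaving the network
  nearly empty.
- **Inflection rule** (the default for the proposed methods): let
  `rho(m)` be the relative connectivity change rate above and
  `delta(m) = rho(m+1) - rho(m)` its discrete rate of change. The selected
  power is the smallest one at which `delta` attains a local extremum — a
  strict sign change of its first difference, or, when `delta` is monotone
  (as for any matrix whose connectivity decays geometrically, e.g. a
  uniform correlation matrix), the grid boundary where its extreme value
  sits, i.e. the second grid power. The relative rate is used deliberately:
  the raw difference sequence `k(m+1) - k(m)` of *any* correlation matrix
  with entries in [0, 1) is a positive mixture of geometric sequences, so
  all of its higher-order differences are strictly monotone and would never
  show an interior extremum. Two guards keep the rule stable: powers where
  `k(m)` has collapsed below 1e-3 of `k(1)` are excluded (round-off wiggles
  there masquerade as extrema), and sign changes below 1e-9 of the change
  rate's magnitude are ignored.

### Tree cut and pruning

Merge heights of the average-linkage dendrogram on `1 - TOM` separate into
tight within-module merges and loose between-module merges. The default
policy ("modules") picks, among the midpoints of all gaps between distinct
merge heights, the flat cut yielding the largest number of clusters of at
least the minimum size, preferring the highest such cut on ties — a
discrete counterpart of "prune by minimum cluster size". Quantile, absolute
height and largest-gap cuts are available as alternatives; measured on
pooled benchmark data a 0.99-quantile cut lands above almost all
between-module merges and returns two clusters, and a fixed absolute height
is reliable only in a narrow power window, which is why neither is the
default. Clusters below the minimum size are dissolved, and each of their
genes is reassigned to the surviving cluster with the smallest average
`1 - TOM` distance (label 0 if none survives). Labels are renumbered by
decreasing size; the whole stage is deterministic.

## Synthetic data

The generator plants `n_clusters` equal clusters of genes, each with V
omics, and draws samples from a multivariate normal with unit variances and
a block correlation matrix parameterised by tau1 (within gene, across
omics), tau2 (same omics, same cluster), tau3 (cross omics, same cluster),
tau4 (between clusters) and tau5 (the perturbation level). In a proportion
p of the clusters (the first `ceil(p * n_clusters)`, deterministically) the
first `n_perturbed_genes` genes have their omics-type-1 correlations with
the other genes of their cluster rewired to tau5, so omics type 1 carries a
discordant signal. Rewiring is cluster-local by default: extending it to
all other genes ("global" scope, also available) makes the matrix lose
positive definiteness whenever tau4 differs from tau5 at the benchmark
parameter levels, so the global reading is not simulable there; with
tau4 = tau5 the two scopes coincide. Positive definiteness is asserted
(smallest eigenvalue > 1e-10) and never repaired — an inconsistent tau
combination fails loudly.

Benchmark conditions (defaults): 50 genes in 10 clusters of 5, V = 3,
Sk = 100 samples per study, K = 5 studies,
(tau1..tau5) = (0.6, 0.4, 0.3, 0.1, 0.1), p = 0.3. Case 2 raises p to 0.5
in the last two studies; case 3 varies (tau1, tau2) per study; scenario 2
swaps tau1 and tau2 and drops Sk to 30. Study draws are seeded through a
`SeedSequence` spawn of the master seed, so runs are bit-reproducible and
studies are mutually independent.

What the generator does **not** emulate: non-Gaussian marginals, count
data, gene-specific correlation heterogeneity, missing omics blocks, or
unequal cluster sizes. Passing benchmarks therefore demonstrate correctness
of the algorithmic chain under the stated correlation model, not robustness
to real-data artefacts.

## Evaluation harness

`run_scenario` replicates simulate → correlate → pool → cluster → score for
a roster of method names and aggregates per-replicate adjusted Rand indices
(ARI; chance-corrected, 1 = perfect recovery). Single-omics baselines
(WGCNA with either power rule, optional K-means with the true cluster count
or a gap-statistic choice) run on omics type 1 of study 1. Replicate
counts: the benchmark checks in the test suite and the acceptance script
use 20 replicates, which keeps the full suite within a few minutes at the
cost of wider standard deviations; the harness default is 100.

## Known limitations

- The study-count sweep saturates early under this implementation: all
  three pooled measures reach mean ARI 1 from two combined studies at the
  benchmark settings, because the modules cut recovers the planted
  structure as soon as the pooled matrix separates the blocks at any scale.
  Implementations whose cut stage is more noise-sensitive need more studies
  for the noisier measures (CC, MOC), and report larger thresholds for them.
- In the weak-signal regime ((0.4, 0.3, 0.3, 0.2, 0.1), Sk = 100) the CC
  and MSOC pooled methods perform within one standard error of each other
  (mean ARI ≈ 0.85); their ordering at 20 replicates is effectively a tie
  and can flip with the seed.
- The full-covariance GLS variant is O(p*^2) memory and O(p*^3) time per
  study and is practical only for modest gene counts; the diagonal variant
  is the intended default and is never less accurate in the benchmarks.
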