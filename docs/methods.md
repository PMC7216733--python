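# Methods

This note documents the statistical procedures, their assumptions, the
defaults that matter, and the choices made where several reasonable
definitions exist.

## Input model and scope

A project couples a gene × sample matrix of non-negative integer counts
with a target table declaring one or two biological factors and an
optional replicate factor.  The design must be **complete** (every
biological condition observed in ≥ 1 sample); replicate counts may be
unbalanced.  Modality order is first appearance in the target file, and
the first modality of each factor is the reference level of the GLM
coding — this affects coefficient values but not condition-mean contrasts.
Sample filtering rules (keep/drop by factor modality) re-validate
completeness and drop factors reduced to a single modality, so a 2-factor
project restricted to one tissue cleanly becomes a 1-factor analysis.
Designs with more than two biological factors are out of scope.  The
replicate factor is treated as crossed (shared modalities across
conditions), not nested.

## Filtering and normalization

Low-count genes are removed on CPM computed from **raw** library sizes
(filtering precedes normalization; factors are then computed on the
filtered matrix).  Two strategies are offered, with these exact semantics
(the names admit more than one reading; the alternative per-condition
counting rule can be obtained by composing `compute_cpm` directly):

- `NbConditions` (default, cutoff 1 CPM): keep gene *g* iff its mean CPM
  within at least one biological condition reaches the cutoff.
- `NbReplicates`: keep *g* iff its CPM reaches the cutoff in at least *r*
  samples, *r* = the minimum replicate count over conditions.

TMM factors follow the published trimmed-mean recipe: reference sample =
the one whose upper-quartile/total ratio is closest to the across-sample
mean of that ratio; per sample, M and A statistics over genes positive in
both sample and reference; two-sided trimming at 30 % (M) and 5 % (A);
inverse asymptotic-binomial-variance weights; factors rescaled to
geometric mean 1.  Trim fractions are exposed as arguments.  RLE is the
median ratio to the per-gene geometric mean over everywhere-expressed
genes.  Both methods are permutation-equivariant and return unit factors
for library-size-only differences; the implementation was verified against
the Bioconductor reference implementations to 10 decimal places on seeded
fixtures (frozen in the test suite).

QC summaries use `log2(normalized count + 1)`: per-sample quartiles,
Ward-linkage dendrogram on Euclidean distances between samples, and
centered (unscaled) PCA via SVD with deterministic axis signs.

## GLM coding and automatic contrasts

Treatment coding with coefficient order: intercept, replicate deviations,
factor-A deviations, factor-B deviations, interaction deviations —
`1 + (R−1) + (I−1) + (J−1) + (I−1)(J−1)` coefficients with interaction.
A warning (not an error) is emitted when the sample count is below twice
the coefficient count.

Contrasts are defined by zero-sum rational weights on condition means at
the reference replicate and realized on the coefficient basis, so
replicate coefficients always receive weight 0.  Three families are
generated for every unordered modality pair, oriented first-declared minus
later-declared: averaged (unweighted mean over the other factor's
modalities — the interpretable quantity under unbalance, rather than
sample-size weighting), per-modality, and interaction
(difference-of-differences).  Output order: A-averaged, A-per-modality,
B-averaged, B-per-modality, interactions.  Under an additive model the
interaction contrasts are identically zero on the coefficient basis; they
are flagged degenerate and excluded by default.

## Negative-binomial inference

Per-gene IRLS with log link, weights `μ/(1+φμ)`, ridge 1e-10 on the normal
equations, step-halving on deviance increase, `|β| ≤ 50`, convergence at
relative deviance change < 1e-8 (max 100 iterations); all-zero genes are
pinned at the floor with `converged=False`.  Fitting is vectorized across
genes.

Dispersion maximizes the Cox–Reid adjusted profile likelihood
(gene log-likelihood at the IRLS fit minus ½ log det of the Fisher
information), searched on a log-scale grid over [1e-4, 10] refined by
golden section — deterministic.  Tagwise estimates maximize
`APL_g(φ) + (prior_df / residual_df) · mean_g APL(φ)` (shared term
spline-interpolated from the grid; per-gene term exact, refined by a
batched golden section), i.e. empirical-Bayes shrinkage toward the common
value with `prior_df = 10` by default.  No abundance trend is modelled —
a deliberate simplification; the estimator is validated against its own
stated objective via grid-search oracles and parameter-recovery
simulations, not against any external package's output.

Each contrast is tested by a likelihood-ratio chi-square with 1 df:
the null fit restricts β to the null space of the contrast vector
(an SVD basis completion), dispersions held fixed; `log2FC = cᵀβ̂ / ln 2`.
BH adjustment is applied within each contrast separately (each contrast is
reported in its own subdirectory); DEG = adjusted p ≤ α (default 0.05).
Raw p-value histograms (20 right-closed bins) carry a tail-uniformity
flag: false when any of the last 4 bins deviates from `m/20` by more than
`3·√(m/20)`, which triggers logged advice to refilter more stringently.
Top-DEG lists sort by raw p, ties by |log2FC| then gene id.

Calibration note: on null simulations with a scalar (common) generating
dispersion, the common-dispersion fit gives near-nominal type-I error;
tagwise shrinkage with few residual df is known to be slightly liberal in
that setting (a property of plug-in dispersion LRTs generally), which is
why the calibration checks use the common fit while power/FDR checks use
the tagwise default.

## Co-expression mixtures

Profiles `p_gj = ỹ_gj / Σ_l ỹ_gl` are built from normalized counts
`ỹ = y · (mean effective size / effective size_j)` (kept on the count
scale so the mean-count filter has familiar units).  Genes with mean
normalized count below 50 (config-exposed) go to Cluster 0.  Profiles are
transformed by `arcsin(√p)` (the variance-stabilizing form of the arcsine
family) and clustered with full-covariance Gaussian mixtures.

EM uses k-means++-seeded, softened (0.9/0.1) initial responsibilities;
every covariance update adds a constant ridge `1e-6 × mean data variance`
to the diagonal (escalated only if Cholesky still fails), which keeps the
likelihood effectively monotone — monotonicity is asserted on every run at
1e-6 relative tolerance.  Small-EM: `n_inits` starts of 10 iterations
each; the best start is run to convergence (relative change < 1e-8, max
1000 iterations).  A per-(loop, K, init) seed ladder makes serial and
parallel execution agree.

Model selection minimizes the soft-entropy ICL
`−2 log L + ν_K log n + 2 Ent`, `ν_K = (K−1) + Kd + Kd(d+1)/2`
(coincides with the hard-assignment variant when posteriors are 0/1, and
with BIC at K = 1).  Loop 1 fits the grid {5, 10, 15, 20, 25, 30} with 5
starts each; loop 2 re-fits `[K*−4, K*+4] ∩ [2, 30]` (±4 spans halfway to
the neighbouring grid points) with 40 starts each and returns the global
loop-2 minimizer.  A convexity flag records whether the loop-2 ICL curve
has a single local minimum; a non-convex curve logs advice to remove
flat-profile genes.  Loop-2 fits are checkpointed per K (JSON) keyed by
seed, start count and a data digest, so interrupted runs resume.
Clusters are relabeled 1..K by decreasing size (ties: lowest original
index); Cluster 0 holds the filtered genes, so labels partition the input
list.

## Enrichment

Exact hypergeometric tails, both including X = k: `p_over = P(X ≥ k)`,
`p_under = P(X ≤ k)`.  The universe defaults to the filtered (expressed)
gene set, config-overridable; list genes outside the universe are dropped
with a warning, and annotation pairs for absent genes are kept at load
time (restriction happens at test time).  BH is applied separately to the
over- and under-representation families — they answer different questions
and are dependent — and is switchable off.  Terms are opaque labels: no
ontology-graph propagation.

## Synthetic data

The generator emulates the kind of complete 2×2×3 factorial (12 samples,
3 replicates) used as the worked example throughout: NB counts with
`Var = μ + φμ²`, baseline log2 means uniform on [3, 12], library-size
multipliers log-normal(0, 0.1), dispersion 0.1 — values typical of plant
bulk RNA-seq replicate variability.  Planted effects add ±`effect_log2`
(default 2, i.e. 4-fold) to one non-reference modality (main effects) or
one non-reference cell (interactions) for disjoint gene subsets; truth for
*any* contrast is derived exactly by applying the contrast's condition
weights to the planted log2 condition means.  The co-expression generator
gives each cluster a distinct condition-concentration pattern (85 % of
expression on a cluster-specific condition subset) with per-gene abundance
drawn log-normally and tight NB noise (φ = 0.05), matching the premise
that co-expression structure is well separated in profile space; total
abundances ~2^10–2^13 keep profiled genes above the Cluster-0 floor.
The annotation generator attaches planted terms to given gene sets plus
Bernoulli background pairs.

What the generator does **not** emulate: mean–dispersion trends, outlier
samples, batch effects, correlated genes outside planted clusters, or
annotation term hierarchies.  Passing recovery tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
real-data violations of it.

## Problem sizes and numerical defaults

Validation simulations use 5000 genes (null calibration), 2000 genes
(power/FDR) and 900 genes / 7 clusters (mixture recovery) — large enough
for the binomial/ARI bands being checked while keeping the full suite
fast on a single CPU.  Key tolerances: IRLS 1e-8, EM 1e-8, dispersion
bracket 1e-6 on log φ, profile row sums 1e-10, LR clipped at −1e-8 → 0.
Ties are broken deterministically everywhere (stable sorts, fixed
dendrogram and relabeling rules, fixed PCA signs), so identical seeded
runs are byte-identical.

## Known limitations

- LRT with plug-in dispersions is mildly liberal at very small replicate
  numbers (see the calibration note); quasi-likelihood F-tests are not
  implemented.
- No dispersion–abundance trend.
- Full-covariance mixtures need cluster sizes comfortably above the sample
  dimension; very small clusters rely on the covariance ridge.
- Enrichment treats terms independently (no graph structure).
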