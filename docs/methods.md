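# Methods

## Scope and data model

The package operates on a merged multi-platform cohort: a genes × samples
matrix of log2 intensities (`ExpressionMatrix`) whose gene universe is the
sorted intersection of the contributing platforms' panels, plus one
metadata record per sample (dataset, platform, clinical group, optional
age and sex). Clinical groups are `HealthyControl`, `Bacteremia` and
`SepticShock`; controls anchor the normalization and the classification
thresholds. Probe-level matrices are collapsed to genes by the per-sample
arithmetic mean of a gene's probes before merging. Per-study
preprocessing (background correction, within-study normalization, log2
transform) is assumed done upstream; gene identifiers are treated as
opaque symbols with no alias resolution.

## Control-anchored co-normalization

`conorm` fits the parametric empirical-Bayes location/scale batch model on
the control samples of each platform only:

    Y_ijg = α_g + γ_ig + δ_ig ε_ijg,   ε ~ N(0, σ_g²)

* α̂_g is the sample-size-weighted grand mean over controls, σ̂_g² the
  pooled variance of residuals from per-platform control means.
* After standardization, per-platform per-gene estimates (γ̂, δ̂²) are
  shrunk toward moment-matched priors — normal for γ (mean γ̄_i, variance
  τ²_i across genes), inverse-gamma for δ² (a_i, b_i from the mean and
  variance of δ̂² across genes) — by the usual fixed-point iteration on
  the conditional posterior means. Tolerance 1e-4 on the max parameter
  change, cap 200 iterations; in practice convergence takes a handful of
  iterations. Degenerate priors (τ² = 0, or non-finite a/b from a
  zero-variance moment match) fall back to the unshrunk estimates.
* The adjustment (standardize, subtract γ\*, divide by √δ\*,
  destandardize) is applied to **all** samples of the platform, cases
  included. Because it is linear per (platform, gene), sample ranks within
  a platform are preserved and the case-minus-control contrast survives up
  to a common per-gene scale.
* Genes with zero pooled control variance cannot be standardized; they are
  flagged and passed through unadjusted rather than erroring, since
  near-constant housekeeping panels are legitimate inputs.
* Platforms with fewer than two control samples are an error: a single
  control cannot inform a scale estimate.
* No covariates (age, sex) enter the model; they are diagnostics, checked
  after the fact, not design terms.

`validate` summarizes what the adjustment did: pooled cross-platform
control variance of housekeeping genes before/after, the case-vs-control
rank-sum contrast of marker genes before/after, the Pearson correlation
between the flattened pre and post matrices, and a per-platform
two-sample Kolmogorov–Smirnov distance between the platform's pooled
values and everyone else's. The flattened-matrix convention for the
Pearson check is one of several defensible readings (per-sample means and
quantiles are alternatives); it is the most stringent of the three.

## Signature scoring and classification

`sigscore` implements four scoring rules: geometric-mean difference of up-
vs down-gene linear expressions (computed as 2^mean(log2) per side),
two-gene log2 ratio, arithmetic mean of marker log2 values, and weighted
linear combination. A sample is called a case when its score is strictly
greater than the linearly interpolated 75th percentile of the control
scores. The strict inequality makes a degenerate (constant) control
distribution classify all controls as 0. AUROC is the Mann–Whitney U
statistic divided by n₁n₂, ties counting ½, computed from the continuous
score (not the binarized label).

Two consequences worth stating plainly: with continuous scores the Q3
rule pins specificity near 0.75 (a quarter of controls always exceed
their own Q3), so overall accuracy is capped near 0.85 at this cohort's
~45% control share; and accuracy is therefore a threshold-convention
statistic, while AUROC measures separation independently of it.

## Pseudotime

`trajectory` is a deliberately simple severity-continuum inference:
anti-log the matrix, re-stabilize with log1p, center, PCA to `num_dim`
(default 50) components; a 2-D view (first two PCs by default, seeded UMAP
behind `backend="umap"`); k-means (default k = 3) on the 2-D embedding; a
minimum spanning tree over cluster centroids; root at the cluster with the
largest control fraction (ties broken toward the larger cluster); each
sample projected onto its nearest tree edge; pseudotime = tree distance
from the root centroid to the projection. Samples beyond a terminal
centroid project onto it and share its pseudotime. The first two PCs are
the default embedding because they are deterministic, fast, and — for a
planted one-dimensional continuum — sufficient; UMAP is kept as an option
for real data with curved manifolds.

Cluster markers are genes with a BH-adjusted cluster-vs-rest rank-sum
q < 0.01 **and** specificity ≥ 0.50, where specificity is the cluster's
mean linear expression divided by the sum of all clusters' means — a
proportion-of-total construction chosen over divergence-based scores for
transparency; the thresholds' semantics are unchanged.

## Differential expression and enrichment

`deg.wilcoxon_deg` computes per-gene two-sided rank-sum p-values: the
exact tail (from the count recurrence for the U distribution, computed
once per group-size pair and looked up vectorized) when both groups have
≤ 25 samples and the gene has no ties, otherwise the tie-corrected,
continuity-corrected normal approximation. log2FC is the difference of
group means of log2 values (so linear FC = 2^log2FC); significance is the
joint gate |log2FC| > 1 and BH q < 0.05, with BH applied per contrast
across all genes. Under a null simulation the raw type-I rate at 0.05 is
0.049 (the exact test's discreteness makes it slightly conservative) and
the joint gate flags essentially nothing.

Over-representation uses the hypergeometric upper tail of drawing ≥ k
set genes in a list of n from a universe of N containing m, after
intersecting each set with the universe and skipping sets with fewer than
3 effective members; BH runs across tested sets. Redundancy reduction is
greedy: visit terms by ascending (q, p, term id) and drop any term whose
Jaccard similarity with an already-kept term exceeds 0.4. This replaces
ontology-graph dispensability — which needs the term DAG — with a
membership-overlap criterion at the same threshold.

`module_expression_summary` pools all log2 values of a module's genes
within each group and attaches a Kruskal–Wallis omnibus p and Dunn's
pairwise rank z-tests (tie-corrected, Bonferroni-adjusted). Dunn's test
is implemented in-package; pooled values within a sample are not strictly
independent, so these p-values describe the pooled distributions, not a
per-sample inference.

## Deconvolution

`deconv` models a bulk profile as a non-negative linear mixture of
cell-type reference columns on the linear scale (log2 input anti-logged as
2^x). Relative mode solves NNLS on the shared marker genes and
renormalizes weights to proportions; fit quality is the Pearson
correlation between the reconstructed and observed marker vector, and a
sample-level permutation p-value (permute the sample's marker values,
re-fit, add-one estimator over `n_perm` ≥ 100 draws) filters samples the
mixture model cannot explain at p < 0.05. Absolute mode fits
unconstrained least squares (Huber-robust behind a flag) and then zeroes
weights with |w| < 1e-3 and excludes cell types with w below −5% of the
total absolute weight — both thresholds are configuration, not facts about
any particular dataset. NNLS replaces support-vector and robust-regression
machinery of the web tools this emulates; it is deterministic, solves the
same linear-mixture model, and is exact at these problem sizes.

## Module classifiers

`modscore.select_features` computes the classic per-tree out-of-bag
permutation importance (mean decrease in accuracy) from a seeded
scikit-learn random forest (default 500 trees): for each tree, each gene
the tree splits on is permuted among the tree's OOB samples and the OOB
accuracy drop is recorded; a gene's importance is its average drop over
all trees, and genes above 0.5% are selected. The per-tree construction
matters: ensemble-level permutation importance assigns near-zero values to
correlated informative genes (the rest of the ensemble compensates),
whereas per-tree OOB importance credits each gene for the trees that
actually used it.

Module scores sum linear expression over the up- and down-gene sets,
normalize each sum by √(set size), and combine as log(P/N) (ratio
variant) or log(|P − N| + 1e-9) (absolute-difference variant), natural
log. The √n normalizers are the package's reading of the published score
constants; the raw constants can be passed explicitly for a literal
reproduction. The ratio score is invariant to global linear-scale
rescaling; the absolute-difference score shifts by log c. Evaluation
reuses the Q3 binarization and confusion/AUROC machinery.

## The synthetic cohort: what it emulates, and what it does not

`synth.generate_cohort` draws per-gene baselines once (uniform 4–12 log2
units), then builds each sample as

    baseline + slope·severity (module genes) + γ_platform + N(0, noise_sd)·δ_platform

Defaults: 5 platforms × (50 controls, 50 bacteremia, 10 septic shock) —
matching the pooled study shape of roughly 46/45/9% controls/bacteremia/
shock — 2000 genes, noise_sd 0.3 log2 units, platform shifts
γ = (0, 1.5, −1.5, 1.0, −1.2) and noise scales δ = (1, 2, 0.7, 1.5, 1.2).
The batch spread deliberately dominates the within-platform noise: that is
the situation that makes cross-platform co-normalization necessary in the
first place, and normalization can only ever remove the between-platform
component. Two modules are planted: a 40-gene hemostasis-like module
rising 2.5 log2 units per unit severity and a 24-gene T-cell-like module
falling 2.0; ten housekeeping genes carry no severity term.

Latent severity is a deterministic quantile grid of Beta(1,8) for
controls, Uniform(0,1) for bacteremia and Beta(8,1) for septic shock,
shared across platforms. Two reasons: platforms with identical group
design then differ only through batch terms and noise (so the degenerate
no-noise case is exactly value-identical across platforms), and the
planted continuum is covered systematically, making recovery benchmarks
stable — the seed perturbs measurement noise, not the ground truth. The
bacteremia group deliberately spans the whole continuum, so a fraction of
bacteremia samples is molecularly control-like; this bounds any
classifier's attainable sensitivity by design, and the module-classifier
accuracies near 0.81 on the default cohort are close to that bound, not a
deficiency of the scoring.

What the generator does **not** emulate: probe-level physics, gene–gene
correlation beyond the planted modules, platform-specific panel
differences (all platforms share the gene universe), non-Gaussian noise,
and any coupling between the cell-mixture generator and the cohort
generator. Passing recovery tests therefore demonstrates correctness of
the estimators under the stated model, not performance on real arrays.

`generate_signature_matrix` builds a marker-structured linear-scale
reference (each type's markers elevated `fold`× over a shared baseline);
`generate_mixtures` mixes bulk profiles as fractions · signatureᵀ with
multiplicative log-normal noise and stores log2(x+1). The deconvolution
stage anti-logs with 2^x; the +1 offset is negligible at the signature
scale used (linear values ≳ 5) and is absorbed by the fit correlation.

## Numerical and testing notes

* Exact rank-sum tails come from the U-distribution count recurrence,
  cached per group-size pair; the implementation is cross-checked against
  an independent library implementation in the tests, as are BH,
  the hypergeometric tail, AUROC and NNLS (against brute-force oracles).
* All stochastic steps (generator, k-means, UMAP, random forest,
  permutation tests) take explicit seeds; same seed, same output.
* Problem sizes in the test suite and the acceptance script (2000-gene
  cohorts, 1000-gene calibration matrices, 100-replicate calibrations,
  n_perm = 1000) were chosen so the whole suite runs in a couple of
  minutes on a laptop while keeping Monte-Carlo error well below the
  asserted margins.
* Known limitations: no missing-value handling (inputs must be complete),
  no reference-batch variant of the batch model, no count-data (RNA-seq)
  model, 2–3-way overlap partitions only, and the pseudotime is a single
  path through cluster centroids — no branching.
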