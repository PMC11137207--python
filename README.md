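# infantsep

Analysis pipeline for multi-study infant-sepsis blood transcriptomes:
cross-platform merging, control-anchored empirical-Bayes co-normalization,
diagnostic gene-signature scoring, severity pseudotime, rank-sum
differential expression with over-representation analysis, immune-mixture
deconvolution, and gene-module classifiers — together with a seeded
synthetic-cohort generator that provides ground truth for every stage.

## Who this is for

Microarray and bulk-RNA studies of infant sepsis are individually small;
pooling public cohorts across platforms is the only way to reach useful
sample sizes, but platform batch effects dwarf the biology. This package
implements the co-normalization and downstream analysis stack for that
setting, and ships a generator of realistic multi-platform cohorts with
known batch effects, a latent severity continuum (healthy control →
bacteremia → septic shock), planted gene modules, and known cell-type
mixtures, so every stage is testable against ground truth.

## The model at the core

Expression of gene *g* in control sample *j* on platform *i* (log2 scale)
is modelled as

    Y_ijg = α_g + γ_ig + δ_ig · ε_ijg,   ε ~ N(0, σ_g²)

with a normal prior on the additive batch effects γ and an inverse-gamma
prior on the multiplicative effects δ², both moment-matched per platform
and solved by the standard fixed-point iteration. The parameters are
estimated **on healthy controls only** and then applied to every sample, so
the within-platform case-minus-control contrast is preserved while
platform bias is removed — the property that makes pooled case/control
comparisons meaningful.

Downstream, samples are scored with published-signature rules (geometric-
mean difference, two-gene log-ratio, marker means, weighted sums) and
binarized at the 3rd quartile of control scores; ordered along a centroid
minimum-spanning-tree pseudotime rooted in the control-rich cluster;
tested per gene with two-sided Wilcoxon rank-sum statistics gated at
|log2FC| > 1 and Benjamini–Hochberg q < 0.05; enriched against gene sets
with the hypergeometric upper tail; and unmixed against a cell-type
signature matrix by non-negative least squares with a permutation
goodness-of-fit filter.

## Worked example

`examples/02_signature_scoring.py` builds the default synthetic cohort
(5 platforms, 550 samples, 2000 genes), co-normalizes it, scores a
geometric-mean-difference signature assembled from the planted severity
modules, and classifies each sample at the control-Q3 threshold:

```
signature: 40 up-genes, 24 down-genes
control-Q3 threshold: 216.32
accuracy 0.811, sensitivity 0.863, specificity 0.748, AUROC 0.902
Kruskal-Wallis omnibus p = 6.53e-64
  control vs bacteremia: Bonferroni-adjusted rank-sum p = 3.18e-49
  control vs shock: Bonferroni-adjusted rank-sum p = 2.19e-28
  bacteremia vs shock: Bonferroni-adjusted rank-sum p = 1.30e-12
```

The accuracy of 0.811 reads as: cases (bacteremia + septic shock) score
above the 75th percentile of the healthy-control score distribution often
enough to classify 81% of all samples correctly; specificity sits near
0.75 because the Q3 rule leaves a quarter of controls above the threshold
by construction. The group comparison shows the score increases
monotonically with clinical severity.

The other `examples/` scripts walk through merging and normalization,
pseudotime, differential expression with enrichment, deconvolution, and
the module classifier, each printing a short interpretation of its output.

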