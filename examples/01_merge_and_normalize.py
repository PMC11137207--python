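"""Merge a multi-platform cohort and co-normalize it on healthy controls.

Generates a small synthetic three-platform cohort with known batch shifts,
estimates the empirical-Bayes batch parameters on controls only, applies
them to every sample, and prints the validation report: the recovered
platform shift, housekeeping-gene variance before/after, and the
pre-vs-post Pearson correlation.
"""

import numpy as np

from infantsep import conorm, synth

cfg = synth.SynthConfig(
    n_platforms=3, n_controls=40, n_bacteremia=30, n_shock=8, n_genes=500,
    batch_gamma=(0.0, 1.5, -1.0), batch_delta=(1.0, 2.0, 0.7),
    severity_effects={
        "inflammation_up": synth.ModuleEffect(tuple(synth.gene_names(500)[20:50]), +2.5)
    },
    housekeeping_genes=tuple(synth.gene_names(500)[:10]),
    noise_sd=0.3, seed=11,
)
cohort, truth = synth.generate_cohort(cfg)
print(f"cohort: {cohort.expr.shape[0]} genes x {cohort.expr.shape[1]} samples "
      f"on platforms {cohort.platforms}")

params = conorm.estimate_params(cohort)
post = conorm.apply(cohort, params)

est_shift = (params.destandardized_shift("PL2") - params.destandardized_shift("PL1")).mean()
print(f"platform PL2 additive shift: injected +1.50, recovered {est_shift:+.3f} log2 units")

report = conorm.validate(
    cohort, post,
    housekeeping=list(cfg.housekeeping_genes[:2]),
    markers=[cfg.severity_effects["inflammation_up"].genes[0]],
)
hk = report.housekeeping
for g in hk.index:
    print(f"housekeeping {g}: control variance {hk.loc[g, 'control_variance_pre']:.2f} "
          f"-> {hk.loc[g, 'control_variance_post']:.2f} after normalization")
print(f"pre-vs-post Pearson r (flattened matrices): {report.pearson_r_pre_post:.3f}")
print("A large variance drop for housekeeping genes with the marker gene's")
print("case-control contrast intact means the batch model removed platform")
print("bias without erasing the disease signal.")
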