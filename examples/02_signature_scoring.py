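"""Score a gene signature and classify samples at the control Q3 threshold.

Builds the default synthetic cohort, scores a geometric-mean-difference
signature assembled from the planted severity modules, binarizes each
sample at the 3rd quartile of the healthy-control scores, and prints the
confusion metrics and AUROC.
"""

from infantsep import conorm, sigscore, synth

cohort, truth = synth.generate_cohort(synth.default_config(seed=0))
post = conorm.apply(cohort, conorm.estimate_params(cohort))

sig = sigscore.SignatureDef(
    name="severity_signature",
    kind="geomean_difference",
    up_genes=list(truth.modules["hemostasis_up"].genes),
    down_genes=list(truth.modules["tcell_down"].genes),
)
scores = sigscore.score(post.expr, sig)
result = sigscore.classify(scores, cohort.control_ids())

print(f"signature: {len(sig.up_genes)} up-genes, {len(sig.down_genes)} down-genes")
print(f"control-Q3 threshold: {result.threshold:.2f}")
print(f"accuracy {result.accuracy:.3f}, sensitivity {result.sensitivity:.3f}, "
      f"specificity {result.specificity:.3f}, AUROC {result.auroc:.3f}")

comparison = sigscore.group_score_comparison(
    scores,
    {
        "control": cohort.group_ids("HealthyControl"),
        "bacteremia": cohort.group_ids("Bacteremia"),
        "shock": cohort.group_ids("SepticShock"),
    },
)
print(f"Kruskal-Wallis omnibus p = {comparison['kruskal_p']:.2e}")
for pair, p in comparison["pairwise_p"].items():
    print(f"  {pair[0]} vs {pair[1]}: Bonferroni-adjusted rank-sum p = {p:.2e}")
print("The Q3 rule fixes specificity near 0.75 by construction; the AUROC")
print("shows the threshold-free separation of cases from controls.")
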