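"""Order samples along a severity pseudotime and find cluster markers.

Embeds the co-normalized cohort with PCA, clusters the 2-D view, builds a
minimum spanning tree over cluster centroids rooted in the control-rich
cluster, and compares the resulting pseudotime with the generator's latent
severity.
"""

import pandas as pd
from scipy.stats import spearmanr

from infantsep import conorm, synth, trajectory

cohort, truth = synth.generate_cohort(synth.default_config(seed=0))
post = conorm.apply(cohort, conorm.estimate_params(cohort))

pcs, embedding = trajectory.embed(post.expr, num_dim=50, seed=0)
labels = trajectory.cluster_samples(embedding, k=3, seed=0)
result = trajectory.pseudotime(embedding, labels, cohort.control_ids(), pcs)

rho = spearmanr(truth.latent_severity.loc[result.pseudotime.index], result.pseudotime)[0]
print(f"root cluster (control-rich): {result.root_cluster}")
print(f"Spearman(latent severity, pseudotime) = {rho:.3f}")

meta = cohort.meta_by_id
table = pd.crosstab(
    result.cluster, pd.Series({s: meta[s].group.value for s in result.cluster.index})
)
print("cluster composition (samples per clinical group):")
print(table.to_string())

markers = trajectory.top_markers(post.expr, labels)
print(f"{len(markers)} cluster markers pass q < 0.01 and specificity >= 0.50")
print("A high Spearman correlation means the tree distance from the control")
print("cluster recovers the planted severity continuum; bacteremia samples")
print("spread across clusters while shock concentrates at the far end.")
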