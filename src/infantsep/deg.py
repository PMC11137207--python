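"""Pairwise differential expression and over-representation analysis.

Differential expression between two sample groups is assessed per gene by a
two-sided Wilcoxon rank-sum test (exact tail for small tie-free groups,
continuity-corrected normal approximation otherwise), with the log2 fold
change taken as the difference of group means of log2 values.  A gene is
significant when |log2FC| > 1 and the Benjamini-Hochberg adjusted p-value
is < 0.05.  Gene lists are then tested for over-representation in annotated
gene sets by the hypergeometric upper tail, with a greedy Jaccard-overlap
reduction standing in for ontology-based redundancy removal.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ExpressionMatrix, GeneSetCollection
from .stats import bh_adjust, dunn_posthoc, kruskal_p, rank_sum_test_matrix

__all__ = [
    "wilcoxon_deg",
    "overlap_partition",
    "ora",
    "redundancy_filter",
    "module_expression_summary",
    "LOG2FC_THRESHOLD",
    "ALPHA",
]

LOG2FC_THRESHOLD = 1.0
ALPHA = 0.05


def wilcoxon_deg(
    expr: ExpressionMatrix,
    group_a_ids: list[str],
    group_b_ids: list[str],
    log2fc_threshold: float = LOG2FC_THRESHOLD,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Per-gene rank-sum differential expression, group A minus group B.

    Returns a table with log2fc, raw p, BH-adjusted p and the joint
    significance gate.  Both groups need >= 3 samples and must not overlap.
    """
    if expr.scale_tag != "log2":
        raise ValueError("differential expression expects log2 input")
    if set(group_a_ids) & set(group_b_ids):
        raise ValueError("groups must not share samples")
    if len(group_a_ids) < 3 or len(group_b_ids) < 3:
        raise ValueError("each group needs at least 3 samples")
    a = expr.values[list(group_a_ids)].to_numpy(dtype=float)
    b = expr.values[list(group_b_ids)].to_numpy(dtype=float)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    _, p = rank_sum_test_matrix(a, b)
    p_adj = bh_adjust(np.clip(p, np.finfo(float).tiny, 1.0))
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "p_adjust": p_adj,
            "significant": (np.abs(log2fc) > log2fc_threshold) & (p_adj < alpha),
        },
        index=expr.gene_ids,
    )
    table.index.name = "gene"
    return table


def overlap_partition(deg_lists: dict[str, list[str]]) -> dict[frozenset, int]:
    """Venn-region counts over 2-3 named gene lists.

    Keys are frozensets of list names marking the membership pattern; values
    are the number of genes in exactly that pattern.  Patterns sum to the
    union size.
    """
    if not 2 <= len(deg_lists) <= 3:
        raise ValueError("overlap partition is defined for 2 or 3 lists")
    names = list(deg_lists)
    sets = {n: set(v) for n, v in deg_lists.items()}
    union = set().union(*sets.values())
    out: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            member = frozenset(combo)
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set().union(*(sets[n] for n in names if n not in combo), set())
            out[member] = len(inside - outside)
    assert sum(out.values()) == len(union)
    return out


def ora(
    gene_list: list[str],
    sets: GeneSetCollection,
    universe: list[str],
    min_set_size: int = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in annotated sets.

    Each set is intersected with the universe; sets with fewer than
    ``min_set_size`` effective members are skipped.  p = upper tail of
    drawing >= k set genes in a list of n from a universe of N containing m.
    BH adjustment runs across the tested sets.
    """
    if not universe:
        raise ValueError("empty universe")
    if not gene_list:
        raise ValueError("empty gene list")
    uni = set(universe)
    if len(uni) != len(universe):
        raise ValueError("universe contains duplicates")
    query = set(gene_list)
    if not query <= uni:
        raise ValueError("gene list must be a subset of the universe")
    N = len(uni)
    n = len(query)
    records = []
    for term_id, (term_name, genes) in sets.sets.items():
        members = set(genes) & uni
        m = len(members)
        if m < min_set_size:
            continue
        overlap = sorted(query & members)
        k = len(overlap)
        p = float(sps.hypergeom.sf(k - 1, N, m, n))
        records.append(
            {
                "term_id": term_id,
                "term_name": term_name,
                "overlap_k": k,
                "set_size_m": m,
                "list_size_n": n,
                "universe_N": N,
                "p": p,
                "contributing_genes": overlap,
            }
        )
    if not records:
        return pd.DataFrame(
            columns=["term_id", "term_name", "overlap_k", "set_size_m",
                     "list_size_n", "universe_N", "p", "p_adjust",
                     "significant", "contributing_genes"]
        ).set_index("term_id")
    table = pd.DataFrame(records).set_index("term_id")
    table["p_adjust"] = bh_adjust(np.clip(table["p"].to_numpy(), np.finfo(float).tiny, 1.0))
    table["significant"] = table["p_adjust"] < alpha
    return table.sort_values(["p_adjust", "p"])


def redundancy_filter(
    enriched: pd.DataFrame,
    sets: GeneSetCollection,
    universe: list[str],
    threshold: float = 0.4,
) -> pd.DataFrame:
    """Greedy redundancy reduction of enriched terms by Jaccard overlap.

    Terms are visited in ascending (p_adjust, p, term_id) order; a term is
    kept unless its Jaccard similarity (on universe-intersected membership)
    with an already-kept term exceeds ``threshold``.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    uni = set(universe)
    order = enriched.sort_values(
        ["p_adjust", "p"], kind="mergesort"
    )
    # deterministic tie-break: stable sort then lexicographic term_id within ties
    order = order.iloc[
        np.lexsort(
            (order.index.to_numpy(), order["p"].to_numpy(), order["p_adjust"].to_numpy())
        )
    ]
    kept: list[str] = []
    kept_members: list[set[str]] = []
    for term_id in order.index:
        members = set(sets.genes(term_id)) & uni
        redundant = False
        for other in kept_members:
            inter = len(members & other)
            union = len(members | other)
            if union and inter / union > threshold:
                redundant = True
                break
        if not redundant:
            kept.append(term_id)
            kept_members.append(members)
    return enriched.loc[kept]


def module_expression_summary(
    expr: ExpressionMatrix,
    module: list[str],
    groups: dict[str, list[str]],
    alpha: float = 0.05,
) -> dict:
    """Pooled module expression per group with Kruskal-Wallis + Dunn tests.

    All log2 values of the module's genes are pooled within each group (the
    per-group distribution a violin of a 40-gene module would show); the
    omnibus Kruskal-Wallis p and Dunn pairwise adjusted p-values are
    attached.
    """
    present = [g for g in module if g in set(expr.gene_ids)]
    if not present:
        raise ValueError("module has no genes in the expression universe")
    if len(present) < len(module):
        warnings.warn(
            f"{len(module) - len(present)} module genes absent from universe",
            stacklevel=2,
        )
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    pooled: dict[str, np.ndarray] = {}
    summary = []
    for name, ids in groups.items():
        vals = expr.values.loc[present, list(ids)].to_numpy(dtype=float).ravel()
        pooled[name] = vals
        summary.append(
            {"group": name, "n_values": vals.size, "mean": float(vals.mean()),
             "sd": float(vals.std(ddof=1))}
        )
    return {
        "module_genes": present,
        "per_group": pd.DataFrame(summary).set_index("group"),
        "values": pooled,
        "kruskal_p": kruskal_p(*pooled.values()),
        "dunn_p": dunn_posthoc(pooled),
        "alpha": alpha,
    }
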