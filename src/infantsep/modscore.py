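"""Gene-module classifiers: importance-based feature selection and the
two square-root-normalized sum scores with Q3-binarized evaluation.

A module is a signed gene set (up- and down-regulated members).  Its score
for a sample sums linear expression over each side, normalizes each sum by
the square root of the side's size, and combines the sides either as a
log-ratio or as the log of the absolute difference.  Feature selection is a
seeded random-forest permutation importance (mean decrease in accuracy),
keeping genes above a 0.5% importance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.ensemble import RandomForestClassifier

from .io import ExpressionMatrix, MergedCohort
from .sigscore import ClassificationResult, classify

__all__ = [
    "ModuleDef",
    "FeatureImportance",
    "load_modules",
    "select_features",
    "module_score",
    "evaluate_module_classifier",
    "IMPORTANCE_THRESHOLD",
]

IMPORTANCE_THRESHOLD = 0.005  # mean decrease accuracy > 0.5%


@dataclass
class ModuleDef:
    """Signed gene module with its score variant."""

    name: str
    pos_genes: list[str] = field(default_factory=list)
    neg_genes: list[str] = field(default_factory=list)
    variant: str = "ratio"  # or "abs_difference"

    def __post_init__(self) -> None:
        if self.variant not in ("ratio", "abs_difference"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if set(self.pos_genes) & set(self.neg_genes):
            raise ValueError("pos and neg gene lists must be disjoint")
        if not (self.pos_genes or self.neg_genes):
            raise ValueError("module needs at least one gene")
        if self.variant == "abs_difference" and not (self.pos_genes and self.neg_genes):
            raise ValueError("abs_difference needs both pos and neg genes")
        if self.variant == "ratio" and not (self.pos_genes and self.neg_genes):
            raise ValueError("ratio needs both pos and neg genes")


def load_modules(path) -> list[ModuleDef]:
    """Load module definitions from YAML ({name, pos, neg, variant} entries)."""
    with open(path, "rt", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return [
        ModuleDef(
            name=e["name"],
            pos_genes=list(e.get("pos", [])),
            neg_genes=list(e.get("neg", [])),
            variant=e.get("variant", "ratio"),
        )
        for e in raw
    ]


@dataclass
class FeatureImportance:
    gene: str
    importance: float  # mean decrease in accuracy, as a fraction
    selected: bool


def select_features(
    expr: ExpressionMatrix,
    labels: pd.Series,
    seed: int = 0,
    threshold: float = IMPORTANCE_THRESHOLD,
    n_estimators: int = 500,
) -> list[FeatureImportance]:
    """Mean-decrease-accuracy feature selection with a seeded random forest.

    Importance is the classic per-tree out-of-bag permutation measure: for
    every tree, a gene's values are permuted among that tree's out-of-bag
    samples and the drop in OOB accuracy is recorded; the gene's importance
    is the average drop over trees.  Computing the drop per tree (rather
    than on the whole ensemble) keeps correlated informative genes visible —
    each earns importance from the trees that actually split on it.  Genes
    above ``threshold`` (default 0.5%) are marked selected.  Deterministic
    given the seed.
    """
    y = labels.loc[expr.sample_ids].to_numpy()
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("labels must contain both classes")
    counts = {c: int((y == c).sum()) for c in classes}
    if min(counts.values()) < 10:
        raise ValueError(f"each class needs >= 10 samples, got {counts}")
    X = expr.values.to_numpy(dtype=float).T  # samples x genes
    n_samples, n_genes = X.shape
    rf = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, bootstrap=True
    )
    rf.fit(X, y)
    rng = np.random.default_rng(seed)
    drops = np.zeros(n_genes)
    for tree, sampled in zip(rf.estimators_, rf.estimators_samples_):
        oob = np.setdiff1d(np.arange(n_samples), sampled)
        if oob.size == 0:
            continue
        X_oob = X[oob]
        y_oob = y[oob]
        base = (tree.predict(X_oob) == y_oob).mean()
        # only features the tree actually splits on can change its output
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        for j in used:
            X_perm = X_oob.copy()
            X_perm[:, j] = X_perm[rng.permutation(oob.size), j]
            drops[j] += base - (tree.predict(X_perm) == y_oob).mean()
    importance = drops / n_estimators
    out = []
    for gene, mda in zip(expr.gene_ids, importance):
        out.append(FeatureImportance(gene, float(mda), bool(mda > threshold)))
    return out


def module_score(
    expr: ExpressionMatrix,
    module: ModuleDef,
    pos_norm: float | None = None,
    neg_norm: float | None = None,
    epsilon: float = 1e-9,
) -> pd.Series:
    """Per-sample module score on sqrt(n)-normalized linear-expression sums.

    P = sum of linear expression over pos genes / sqrt(|pos|), N likewise
    over neg genes; ratio variant -> log(P/N); abs_difference variant ->
    log(|P - N| + epsilon).  ``pos_norm``/``neg_norm`` override the sqrt(n)
    normalizers for literal published constants.
    """
    missing = [
        g for g in [*module.pos_genes, *module.neg_genes] if g not in set(expr.gene_ids)
    ]
    if missing:
        raise KeyError(f"module {module.name}: genes missing from matrix: {missing}")
    vals = expr.values
    linear = np.exp2(vals.to_numpy(dtype=float)) if expr.scale_tag == "log2" else vals.to_numpy(dtype=float)
    lin = pd.DataFrame(linear, index=vals.index, columns=vals.columns)
    p_norm = pos_norm if pos_norm is not None else np.sqrt(len(module.pos_genes))
    n_norm = neg_norm if neg_norm is not None else np.sqrt(len(module.neg_genes))
    P = lin.loc[module.pos_genes].sum(axis=0) / p_norm
    N = lin.loc[module.neg_genes].sum(axis=0) / n_norm
    if module.variant == "ratio":
        if (N <= 0).any():
            raise ValueError(f"module {module.name}: non-positive denominator sum")
        s = np.log(P / N)
    else:
        s = np.log(np.abs(P - N) + epsilon)
    return pd.Series(np.asarray(s, dtype=float), index=expr.sample_ids, name=module.name)


def evaluate_module_classifier(
    scores: pd.Series, cohort: MergedCohort
) -> ClassificationResult:
    """Q3-binarized classification of module scores against clinical truth.

    Cases are bacteremia plus septic shock; the threshold is the 3rd
    quartile of the healthy-control scores; accuracy, sensitivity,
    specificity and AUROC are reported.
    """
    return classify(scores, cohort.control_ids())
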