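"""Diagnostic gene-signature scoring and Q3-binarized classification.

Published sepsis signatures reduce a sample's expression profile to one
scalar: a geometric-mean difference of up- vs down-regulated genes (the
metascore family), a two-gene log-ratio, a plain mean of marker genes, or a
weighted linear combination.  A sample is then called a Case when its score
exceeds the 3rd quartile of the healthy-control scores, and performance is
summarized by accuracy/sensitivity/specificity and the AUROC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .io import ExpressionMatrix
from .stats import kruskal_p, pairwise_rank_sum

__all__ = [
    "SignatureDef",
    "ClassificationResult",
    "load_signatures",
    "score",
    "binarize_q3",
    "confusion_metrics",
    "auroc",
    "classify",
    "group_score_comparison",
]

_KINDS = ("geomean_difference", "two_gene_ratio", "mean_of_markers", "linear_combination")


@dataclass
class SignatureDef:
    """A named gene signature with its scoring rule."""

    name: str
    kind: str
    up_genes: list[str] = field(default_factory=list)
    down_genes: list[str] = field(default_factory=list)
    weights: list[float] | None = None  # linear_combination only, over up_genes

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown signature kind {self.kind!r}")
        if self.kind == "two_gene_ratio":
            if len(self.up_genes) != 1 or len(self.down_genes) != 1:
                raise ValueError("two_gene_ratio needs exactly one up and one down gene")
        elif self.kind == "geomean_difference":
            if not self.up_genes or not self.down_genes:
                raise ValueError("geomean_difference needs non-empty up and down lists")
        elif self.kind == "mean_of_markers":
            if not (self.up_genes or self.down_genes):
                raise ValueError("mean_of_markers needs at least one gene")
        elif self.kind == "linear_combination":
            if not self.up_genes:
                raise ValueError("linear_combination needs genes")
            if self.weights is None or len(self.weights) != len(self.up_genes):
                raise ValueError("linear_combination needs one weight per gene")


def load_signatures(path) -> list[SignatureDef]:
    """Load signature definitions from a YAML file (a list of mappings with
    keys name, kind, up, down, weights)."""
    with open(path, "rt", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    out = []
    for entry in raw:
        out.append(
            SignatureDef(
                name=entry["name"],
                kind=entry["kind"],
                up_genes=list(entry.get("up", [])),
                down_genes=list(entry.get("down", [])),
                weights=entry.get("weights"),
            )
        )
    return out


def _resolve(expr: ExpressionMatrix, genes: list[str], policy: str, sig_name: str) -> list[str]:
    present = [g for g in genes if g in set(expr.gene_ids)]
    missing = [g for g in genes if g not in set(expr.gene_ids)]
    if missing:
        if policy == "error":
            raise KeyError(f"signature {sig_name}: genes missing from matrix: {missing}")
        warnings.warn(
            f"signature {sig_name}: dropping missing genes {missing}", stacklevel=3
        )
    return present


def score(
    expr: ExpressionMatrix, sig: SignatureDef, missing_policy: str = "error"
) -> pd.Series:
    """Per-sample signature score.

    log2 input is anti-logged where the rule operates on the linear scale
    (geometric-mean difference); the two-gene ratio and mean/linear rules
    operate directly on log2 values.
    """
    if expr.scale_tag != "log2":
        raise ValueError("signature scoring expects log2 input")
    if missing_policy not in ("error", "drop"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    vals = expr.values
    up = _resolve(expr, sig.up_genes, missing_policy, sig.name)
    down = _resolve(expr, sig.down_genes, missing_policy, sig.name)

    if sig.kind == "geomean_difference":
        if not up or not down:
            raise KeyError(f"signature {sig.name}: empty gene list after drop")
        # geometric mean of linear values == 2 ** (mean of log2 values)
        g_up = np.exp2(vals.loc[up].mean(axis=0))
        g_down = np.exp2(vals.loc[down].mean(axis=0))
        s = g_up - g_down
    elif sig.kind == "two_gene_ratio":
        s = vals.loc[up[0]] - vals.loc[down[0]]
    elif sig.kind == "mean_of_markers":
        genes = up + down
        if not genes:
            raise KeyError(f"signature {sig.name}: empty gene list after drop")
        s = vals.loc[genes].mean(axis=0)
    else:  # linear_combination
        w = {g: wt for g, wt in zip(sig.up_genes, sig.weights or [])}
        if not up:
            raise KeyError(f"signature {sig.name}: empty gene list after drop")
        s = sum(vals.loc[g] * w[g] for g in up)
    s = pd.Series(np.asarray(s, dtype=float), index=expr.sample_ids, name=sig.name)
    return s


def binarize_q3(scores: pd.Series, control_ids: list[str]) -> tuple[pd.Series, float]:
    """Binarize scores at the 3rd quartile of the control scores.

    Threshold = linearly interpolated 75th percentile of control scores;
    prediction is 1 iff score is strictly greater than the threshold (so a
    degenerate control distribution classifies controls as 0).
    """
    controls = [s for s in control_ids if s in scores.index]
    if not controls:
        raise ValueError("no control samples among the scores")
    if len(controls) < 4:
        raise ValueError("need at least 4 control samples for a stable 3rd quartile")
    threshold = float(np.percentile(scores.loc[controls].to_numpy(), 75))
    pred = (scores > threshold).astype(int)
    return pred, threshold


def confusion_metrics(pred, truth) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) from 0/1 predictions and truth."""
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth must have equal length")
    if truth.min() == truth.max():
        raise ValueError("truth must contain both classes")
    tp = int(((pred == 1) & (truth == 1)).sum())
    tn = int(((pred == 0) & (truth == 0)).sum())
    fp = int(((pred == 1) & (truth == 0)).sum())
    fn = int(((pred == 0) & (truth == 1)).sum())
    return (
        (tp + tn) / truth.size,
        tp / (tp + fn),
        tn / (tn + fp),
    )


def auroc(scores, truth) -> float:
    """Area under the ROC curve via the Mann-Whitney U identity.

    Equals P(score_case > score_control) + 0.5 P(tie); ties contribute 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if truth.min() == truth.max():
        raise ValueError("truth must contain both classes")
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


@dataclass
class ClassificationResult:
    """Q3-binarized classification outcome for one score vector."""

    threshold: float
    predictions: pd.Series
    accuracy: float
    sensitivity: float
    specificity: float
    auroc: float


def classify(scores: pd.Series, control_ids: list[str]) -> ClassificationResult:
    """Binarize at the control Q3 and evaluate against control/case truth.

    Truth is implied by ``control_ids``: controls are 0, all other samples 1.
    The AUROC uses the continuous score.
    """
    truth = pd.Series(
        [0 if s in set(control_ids) else 1 for s in scores.index], index=scores.index
    )
    pred, threshold = binarize_q3(scores, control_ids)
    acc, sens, spec = confusion_metrics(pred.to_numpy(), truth.to_numpy())
    return ClassificationResult(
        threshold=threshold,
        predictions=pred,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        auroc=auroc(scores.to_numpy(), truth.to_numpy()),
    )


def group_score_comparison(
    scores: pd.Series, groups: dict[str, list[str]], adjust: str = "bonferroni"
) -> dict:
    """Kruskal-Wallis omnibus plus pairwise rank-sum tests on signature scores.

    Groups with fewer than 2 members are excluded with a warning.  Pairwise
    p-values are Bonferroni-adjusted by default.
    """
    usable = {}
    for name, ids in groups.items():
        present = [s for s in ids if s in scores.index]
        if len(present) < 2:
            warnings.warn(f"group {name!r} has <2 samples; excluded", stacklevel=2)
            continue
        usable[name] = scores.loc[present].to_numpy()
    if len(usable) < 2:
        raise ValueError("need at least two groups of size >= 2")
    return {
        "kruskal_p": kruskal_p(*usable.values()),
        "pairwise_p": pairwise_rank_sum(usable, adjust=adjust),
    }
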