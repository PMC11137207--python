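"""Bulk immune-mixture deconvolution.

A bulk blood transcriptome is modelled as a non-negative linear mixture of
cell-type reference profiles (an LM22-style signature matrix).  Relative
mode solves non-negative least squares on the shared marker genes and
renormalizes the weights to proportions; goodness of fit is summarized by
the Pearson correlation between the reconstructed and observed marker
vector, with a permutation p-value used to drop samples the mixture model
cannot explain.  Absolute mode fits unconstrained (optionally Huber-robust)
weights and applies zeroing/exclusion rules for small or negative values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import nnls

from .io import ExpressionMatrix
from .stats import bh_adjust, kruskal_p, rank_sum_test

__all__ = [
    "SignatureMatrixRef",
    "MixtureFractions",
    "deconvolve",
    "deconvolve_matrix",
    "permutation_fit_p",
    "absolute_postprocess",
    "group_compare",
]


@dataclass
class SignatureMatrixRef:
    """Cell-type reference: genes x cell-types expected linear-scale expression."""

    values: pd.DataFrame  # index = marker genes, columns = cell types

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if (v < 0).any():
            raise ValueError("signature values must be non-negative")
        if (v.sum(axis=0) == 0).any():
            raise ValueError("signature contains an all-zero cell-type column")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate marker genes in signature")

    @property
    def cell_types(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def genes(self) -> list[str]:
        return self.values.index.tolist()

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.values.to_numpy(dtype=float)))


@dataclass
class MixtureFractions:
    """Per-sample cell-type proportions with fit statistics."""

    fractions: pd.DataFrame  # samples x cell types, rows sum to 1
    fit_correlation: pd.Series
    fit_p: pd.Series | None = None
    excluded_types: list[str] = field(default_factory=list)

    def retained(self, alpha: float = 0.05) -> "MixtureFractions":
        """Samples passing the permutation goodness-of-fit filter."""
        if self.fit_p is None:
            raise ValueError("fit p-values were not computed")
        keep = self.fit_p.index[self.fit_p < alpha]
        return MixtureFractions(
            self.fractions.loc[keep],
            self.fit_correlation.loc[keep],
            self.fit_p.loc[keep],
            list(self.excluded_types),
        )


def _to_linear(x: np.ndarray, scale_tag: str) -> np.ndarray:
    return np.exp2(x) if scale_tag == "log2" else x


def _shared_markers(expr: ExpressionMatrix, sig: SignatureMatrixRef) -> list[str]:
    shared = [g for g in sig.genes if g in set(expr.gene_ids)]
    k = len(sig.cell_types)
    if len(shared) < k:
        raise ValueError(
            f"only {len(shared)} marker genes shared with the signature; "
            f"need at least {k}"
        )
    if len(shared) < 2 * k:
        import warnings

        warnings.warn(
            f"only {len(shared)} shared marker genes for {k} cell types; "
            "estimates may be unstable",
            stacklevel=2,
        )
    return shared


def _fit_sample(y: np.ndarray, S: np.ndarray, mode: str) -> np.ndarray:
    if mode == "relative":
        w, _ = nnls(S, y)
    elif mode == "absolute":
        w, *_ = np.linalg.lstsq(S, y, rcond=None)
    elif mode == "absolute_huber":
        import statsmodels.api as sm

        w = sm.RLM(y, S, M=sm.robust.norms.HuberT()).fit().params
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return np.asarray(w, dtype=float)


def deconvolve(
    sample_expr: pd.Series | np.ndarray,
    sig: SignatureMatrixRef,
    mode: str = "relative",
) -> tuple[np.ndarray, float]:
    """Unmix one linear-scale marker-gene vector against the signature.

    Returns ``(raw_weights, fit_correlation)`` where fit_correlation is the
    Pearson r between the reconstructed (S @ w) and observed marker vector.
    Relative fractions are ``weights / weights.sum()``.
    """
    S = sig.values.to_numpy(dtype=float)
    y = np.asarray(sample_expr, dtype=float)
    if y.shape[0] != S.shape[0]:
        raise ValueError("sample vector length must match signature gene count")
    w = _fit_sample(y, S, mode)
    recon = S @ w
    if np.std(recon) == 0 or np.std(y) == 0:
        r = 0.0
    else:
        r = float(sps.pearsonr(recon, y)[0])
    return w, r


def deconvolve_matrix(
    expr: ExpressionMatrix,
    sig: SignatureMatrixRef,
    mode: str = "relative",
    n_perm: int | None = None,
    seed: int = 0,
) -> MixtureFractions:
    """Deconvolve every sample of a cohort matrix.

    Log2 input is anti-logged (2^x) before fitting.  When ``n_perm`` is set,
    a permutation goodness-of-fit p-value is computed per sample.
    """
    shared = _shared_markers(expr, sig)
    sig_shared = SignatureMatrixRef(sig.values.loc[shared])
    lin = _to_linear(expr.values.loc[shared].to_numpy(dtype=float), expr.scale_tag)
    rows, cors, pvals = [], [], []
    rng = np.random.default_rng(seed)
    for j, sample in enumerate(expr.sample_ids):
        y = lin[:, j]
        w, r = deconvolve(y, sig_shared, mode=mode)
        total = w.sum()
        frac = w / total if total > 0 else np.full_like(w, np.nan)
        rows.append(frac)
        cors.append(r)
        if n_perm is not None:
            pvals.append(
                permutation_fit_p(
                    y, sig_shared, n_perm=n_perm, seed=int(rng.integers(2**31 - 1)), mode=mode
                )
            )
    fractions = pd.DataFrame(rows, index=expr.sample_ids, columns=sig_shared.cell_types)
    return MixtureFractions(
        fractions=fractions,
        fit_correlation=pd.Series(cors, index=expr.sample_ids),
        fit_p=pd.Series(pvals, index=expr.sample_ids) if n_perm is not None else None,
    )


def permutation_fit_p(
    sample_expr: np.ndarray,
    sig: SignatureMatrixRef,
    n_perm: int = 1000,
    seed: int = 0,
    mode: str = "relative",
) -> float:
    """Permutation p-value of the deconvolution fit correlation.

    The sample's marker-gene values are permuted ``n_perm`` times; the
    add-one estimator p = (1 + #{r_perm >= r_obs}) / (1 + n_perm) is
    returned.  Requires ``n_perm >= 100``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    y = np.asarray(sample_expr, dtype=float)
    _, r_obs = deconvolve(y, sig, mode=mode)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        _, r = deconvolve(rng.permutation(y), sig, mode=mode)
        if r >= r_obs:
            count += 1
    return (1 + count) / (1 + n_perm)


def absolute_postprocess(
    raw_weights: np.ndarray | pd.Series,
    cell_types: list[str] | None = None,
    epsilon_zero: float = 1e-3,
    epsilon_exclude: float = 0.05,
) -> tuple[np.ndarray, list[str]]:
    """Clean unconstrained (absolute-mode) weights.

    Weights with |w| < ``epsilon_zero`` are set to zero; weights below
    ``-epsilon_exclude`` (fraction of total absolute weight) mark the cell
    type for exclusion.  Returns ``(cleaned_weights, excluded_types)``.
    """
    w = np.asarray(raw_weights, dtype=float).copy()
    if cell_types is None:
        cell_types = [f"type_{i}" for i in range(w.size)]
    total = np.abs(w).sum()
    scale = total if total > 0 else 1.0
    excluded = []
    for i in range(w.size):
        if abs(w[i]) < epsilon_zero:
            w[i] = 0.0
        elif w[i] < -epsilon_exclude * scale:
            excluded.append(cell_types[i])
    return w, excluded


def group_compare(
    fractions: MixtureFractions,
    groups: dict[str, list[str]],
    alpha: float = 0.05,
    min_group: int = 3,
) -> pd.DataFrame:
    """Per-cell-type Kruskal-Wallis across groups with BH across cell types.

    Groups that drop below two retained samples are excluded with a warning
    (the behaviour seen when a clinical group fails the fit filter almost
    entirely).  Returns a table with omnibus p, BH-adjusted p, significance
    stars, and pairwise rank-sum p-values.
    """
    import warnings

    frac = fractions.fractions
    usable: dict[str, list[str]] = {}
    for name, ids in groups.items():
        present = [s for s in ids if s in frac.index]
        if len(present) < min_group:
            warnings.warn(
                f"group {name!r} has {len(present)} retained samples; excluded",
                stacklevel=2,
            )
            continue
        usable[name] = present
    if len(usable) < 2:
        raise ValueError("need at least two groups with enough retained samples")

    records = []
    for ct in frac.columns:
        arrays = {g: frac.loc[ids, ct].to_numpy() for g, ids in usable.items()}
        p_omni = kruskal_p(*arrays.values())
        pair_p = {
            f"p_{a}_vs_{b}": rank_sum_test(arrays[a], arrays[b])
            for i, a in enumerate(usable)
            for b in list(usable)[i + 1 :]
        }
        records.append({"cell_type": ct, "p_kruskal": p_omni, **pair_p})
    table = pd.DataFrame(records).set_index("cell_type")
    table["p_adjust"] = bh_adjust(table["p_kruskal"].to_numpy())
    table["significant"] = table["p_adjust"] < alpha
    table["stars"] = [_stars(p) for p in table["p_adjust"]]
    return table


def _stars(p: float) -> str:
    for thresh, mark in [(1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")]:
        if p < thresh:
            return mark
    return ""
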