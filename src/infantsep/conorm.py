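"""Control-anchored empirical-Bayes co-normalization across platforms.

The estimator fits the parametric ComBat location/scale model on the
healthy-control samples of each platform only, then applies the resulting
per-(platform, gene) linear adjustment to every sample — controls and cases
alike.  Because batch parameters are learned where the biological signal is
(assumed) absent, the case-minus-control contrast within each platform is
preserved up to a common per-gene scale, which is the property that makes
cross-platform case/control comparisons meaningful afterwards.

Model, per control sample j of platform i and gene g (log2 scale):

    Y_ijg = alpha_g + gamma_ig + delta_ig * eps_ijg,   eps ~ N(0, sigma_g^2)

gamma_ig receives a normal prior (moment-matched mean gamma_bar_i and
variance tau2_i across genes), delta_ig^2 an inverse-gamma prior
(moment-matched a_prior_i, b_prior_i); the posterior conditional modes
(gamma*, delta*) are found by the standard fixed-point iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ExpressionMatrix, MergedCohort
from .stats import rank_sum_test

__all__ = ["ComBatParams", "NormalizationReport", "estimate_params", "apply", "validate"]

FIXED_POINT_TOL = 1e-4
FIXED_POINT_MAX_ITER = 200


@dataclass
class ComBatParams:
    """Per-gene standardization plus per-platform EB-shrunk batch effects."""

    gene_ids: list[str]
    platforms: list[str]
    alpha_hat: np.ndarray  # per-gene grand mean over controls (log2)
    sigma_hat: np.ndarray  # per-gene pooled control SD
    gamma_star: pd.DataFrame  # platforms x genes, standardized units
    delta_star: pd.DataFrame  # platforms x genes, > 0
    hyperparams: pd.DataFrame  # per platform: gamma_bar, tau2, a_prior, b_prior
    unadjusted_genes: list[str] = field(default_factory=list)

    def destandardized_shift(self, platform: str) -> pd.Series:
        """Additive batch shift of a platform on the log2 scale, per gene."""
        return pd.Series(
            self.gamma_star.loc[platform].to_numpy() * self.sigma_hat,
            index=self.gene_ids,
        )


def _control_blocks(cohort: MergedCohort) -> dict[str, np.ndarray]:
    controls = set(cohort.control_ids())
    blocks = {}
    for p in cohort.platforms:
        ids = [s for s in cohort.sample_ids_of_platform(p) if s in controls]
        blocks[p] = cohort.expr.values[ids].to_numpy(dtype=float)
    return blocks


def estimate_params(cohort: MergedCohort) -> ComBatParams:
    """Estimate batch parameters on healthy controls only.

    Requires >=2 platforms, each with >=2 control samples.  Genes with zero
    pooled control variance are flagged and later passed through unadjusted.
    """
    platforms = cohort.platforms
    if len(platforms) < 2:
        raise ValueError("co-normalization requires at least two platforms")
    blocks = _control_blocks(cohort)
    for p, block in blocks.items():
        if block.shape[1] < 2:
            raise ValueError(f"platform {p} has fewer than 2 control samples")

    genes = cohort.expr.gene_ids
    n_genes = len(genes)
    ns = np.array([blocks[p].shape[1] for p in platforms])
    N = int(ns.sum())

    batch_means = np.stack([blocks[p].mean(axis=1) for p in platforms])  # platforms x genes
    alpha_hat = (ns[:, None] * batch_means).sum(axis=0) / N
    # pooled variance of residuals from the per-platform control means
    ss = np.zeros(n_genes)
    for i, p in enumerate(platforms):
        ss += ((blocks[p] - batch_means[i][:, None]) ** 2).sum(axis=1)
    sigma2 = ss / N
    zero_var = sigma2 <= 0
    sigma_hat = np.sqrt(np.where(zero_var, 1.0, sigma2))

    gamma_star = np.zeros((len(platforms), n_genes))
    delta_star = np.ones((len(platforms), n_genes))
    hyper_rows = []
    for i, p in enumerate(platforms):
        Z = (blocks[p] - alpha_hat[:, None]) / sigma_hat[:, None]
        n_i = Z.shape[1]
        g_hat = Z.mean(axis=1)
        d_hat = Z.var(axis=1, ddof=1)
        gamma_bar = float(g_hat.mean())
        tau2 = float(g_hat.var(ddof=1))
        m = float(d_hat.mean())
        s2 = float(d_hat.var(ddof=1))
        a_prior = (2.0 * s2 + m**2) / s2 if s2 > 0 else np.inf
        b_prior = (m * s2 + m**3) / s2 if s2 > 0 else np.inf
        g_star, d_star = _fixed_point(Z, g_hat, d_hat, gamma_bar, tau2, a_prior, b_prior)
        gamma_star[i] = g_star
        delta_star[i] = d_star
        hyper_rows.append(
            {"platform": p, "gamma_bar": gamma_bar, "tau2": tau2,
             "a_prior": a_prior, "b_prior": b_prior, "n_controls": n_i}
        )

    gamma_star[:, zero_var] = 0.0
    delta_star[:, zero_var] = 1.0
    return ComBatParams(
        gene_ids=genes,
        platforms=list(platforms),
        alpha_hat=alpha_hat,
        sigma_hat=np.where(zero_var, 0.0, sigma_hat),
        gamma_star=pd.DataFrame(gamma_star, index=platforms, columns=genes),
        delta_star=pd.DataFrame(delta_star, index=platforms, columns=genes),
        hyperparams=pd.DataFrame(hyper_rows).set_index("platform"),
        unadjusted_genes=[g for g, z in zip(genes, zero_var) if z],
    )


def _fixed_point(Z, g_hat, d_hat, gamma_bar, tau2, a_prior, b_prior,
                 tol: float = FIXED_POINT_TOL, max_iter: int = FIXED_POINT_MAX_ITER):
    """Solve the EB posterior-mode equations for one platform (vectorized
    over genes).  Degenerate priors (tau2 = 0 or infinite a/b) fall back to
    the unshrunk estimates."""
    n = Z.shape[1]
    if not np.isfinite(a_prior) or not np.isfinite(b_prior) or tau2 <= 0:
        return g_hat.copy(), np.maximum(d_hat, np.finfo(float).tiny)
    g_old = g_hat.copy()
    d_old = d_hat.copy()
    for _ in range(max_iter):
        g_new = (n * tau2 * g_hat + d_old * gamma_bar) / (n * tau2 + d_old)
        sum2 = ((Z - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b_prior) / (n / 2.0 + a_prior - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old)), np.max(np.abs(d_new - d_old))
        )
        g_old, d_old = g_new, d_new
        if change <= tol:
            break
    return g_old, np.maximum(d_old, np.finfo(float).tiny)


def apply(cohort: MergedCohort, params: ComBatParams) -> MergedCohort:
    """Apply the control-estimated adjustment to every sample.

    Per platform b and gene g:
    standardize with (alpha, sigma), subtract gamma*_bg, divide by
    sqrt(delta*_bg), destandardize.  Flagged zero-variance genes pass
    through unchanged.
    """
    if params.gene_ids != cohort.expr.gene_ids:
        raise ValueError("params were estimated on a different gene universe")
    missing = [p for p in cohort.platforms if p not in params.gamma_star.index]
    if missing:
        raise ValueError(f"platforms absent from params: {missing}")
    out = cohort.expr.values.copy()
    skip = np.isin(params.gene_ids, params.unadjusted_genes)
    adjust = ~skip
    alpha = params.alpha_hat[adjust]
    sigma = params.sigma_hat[adjust]
    for p in cohort.platforms:
        ids = cohort.sample_ids_of_platform(p)
        block = out.loc[:, ids].to_numpy(dtype=float)
        g = params.gamma_star.loc[p].to_numpy()[adjust]
        d = params.delta_star.loc[p].to_numpy()[adjust]
        Z = (block[adjust] - alpha[:, None]) / sigma[:, None]
        Z = (Z - g[:, None]) / np.sqrt(d)[:, None]
        block[adjust] = Z * sigma[:, None] + alpha[:, None]
        out.loc[:, ids] = block
    return MergedCohort(
        expr=ExpressionMatrix(out, cohort.expr.scale_tag),
        meta=list(cohort.meta),
        provenance=dict(cohort.provenance),
    )


@dataclass
class NormalizationReport:
    """Validation summary comparing a cohort before and after adjustment."""

    pearson_r_pre_post: float
    housekeeping: pd.DataFrame  # per gene: control variance pre/post
    markers: pd.DataFrame  # per gene: case-vs-control effect and p, pre/post
    ecdf_distance: pd.DataFrame  # per platform: KS distance pre/post
    skipped_panel_genes: list[str] = field(default_factory=list)


def _cross_platform_control_variance(cohort: MergedCohort, gene: str) -> float:
    vals = cohort.expr.values.loc[gene, cohort.control_ids()].to_numpy(dtype=float)
    return float(vals.var(ddof=1))


def validate(
    pre: MergedCohort,
    post: MergedCohort,
    housekeeping: list[str],
    markers: list[str],
) -> NormalizationReport:
    """Report how co-normalization changed the cohort.

    Covers (a) pooled cross-platform control variance of each housekeeping
    gene pre vs post, (b) the case-vs-control rank-sum contrast of each
    marker gene pre vs post, (c) the Pearson correlation between the
    flattened pre and post matrices, and (d) the per-platform two-sample
    Kolmogorov distance between a platform's pooled values and all other
    platforms', pre vs post.
    """
    import warnings

    if not housekeeping or not markers:
        raise ValueError("housekeeping and marker panels must be non-empty")
    universe = set(pre.expr.gene_ids)
    skipped = [g for g in [*housekeeping, *markers] if g not in universe]
    for g in skipped:
        warnings.warn(f"panel gene {g} absent from cohort; skipped", stacklevel=2)
    hk = [g for g in housekeeping if g in universe]
    mk = [g for g in markers if g in universe]

    flat_pre = pre.expr.values.to_numpy(dtype=float).ravel()
    flat_post = post.expr.values.to_numpy(dtype=float).ravel()
    r = float(sps.pearsonr(flat_pre, flat_post)[0])

    hk_rows = []
    for g in hk:
        hk_rows.append(
            {"gene": g,
             "control_variance_pre": _cross_platform_control_variance(pre, g),
             "control_variance_post": _cross_platform_control_variance(post, g)}
        )
    hk_df = pd.DataFrame(hk_rows).set_index("gene") if hk_rows else pd.DataFrame()

    ctrl = pre.control_ids()
    case = pre.case_ids()
    mk_rows = []
    for g in mk:
        row = {"gene": g}
        for tag, cohort_ in (("pre", pre), ("post", post)):
            c = cohort_.expr.values.loc[g, ctrl].to_numpy(dtype=float)
            k = cohort_.expr.values.loc[g, case].to_numpy(dtype=float)
            row[f"effect_{tag}"] = float(k.mean() - c.mean())
            row[f"p_{tag}"] = rank_sum_test(k, c)
        mk_rows.append(row)
    mk_df = pd.DataFrame(mk_rows).set_index("gene") if mk_rows else pd.DataFrame()

    ecdf_rows = []
    for p in pre.platforms:
        row = {"platform": p}
        for tag, cohort_ in (("pre", pre), ("post", post)):
            ids = cohort_.sample_ids_of_platform(p)
            others = [s for s in cohort_.expr.sample_ids if s not in set(ids)]
            a = cohort_.expr.values[ids].to_numpy(dtype=float).ravel()
            b = cohort_.expr.values[others].to_numpy(dtype=float).ravel()
            row[f"ks_{tag}"] = float(sps.ks_2samp(a, b).statistic)
        ecdf_rows.append(row)
    ecdf_df = pd.DataFrame(ecdf_rows).set_index("platform")

    return NormalizationReport(
        pearson_r_pre_post=r,
        housekeeping=hk_df,
        markers=mk_df,
        ecdf_distance=ecdf_df,
        skipped_panel_genes=skipped,
    )
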