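"""Shared nonparametric statistics helpers.

Benjamini-Hochberg step-up and the two-sided Mann-Whitney rank-sum p-value
(exact small-sample tail or continuity-corrected normal approximation) are
authored here because every stage of the pipeline gates on them; the exact
null distribution is computed once per group-size pair via the standard
count recurrence so that thousands of genes can be tested with vectorized
lookups.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import stats as sps

__all__ = [
    "bh_adjust",
    "mwu_exact_sf",
    "rank_sum_test",
    "rank_sum_test_matrix",
    "kruskal_p",
    "pairwise_rank_sum",
    "dunn_posthoc",
]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, in the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(p <= 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


@lru_cache(maxsize=32)
def _mwu_counts(n1: int, n2: int) -> np.ndarray:
    """Number of rank arrangements giving each U value, for U = 0..n1*n2.

    Standard recurrence c(m, n, u) = c(m-1, n, u-n) + c(m, n-1, u) with
    c(m, 0, 0) = c(0, n, 0) = 1 (the Gaussian-binomial coefficient build-up).
    """
    max_u = n1 * n2
    base = np.zeros(max_u + 1)
    base[0] = 1.0
    prev = [base.copy() for _ in range(n2 + 1)]  # m = 0 row
    for m in range(1, n1 + 1):
        cur = [base.copy()]
        for n in range(1, n2 + 1):
            shifted = np.zeros(max_u + 1)
            shifted[n:] = prev[n][: max_u + 1 - n]
            cur.append(shifted + cur[n - 1])
        prev = cur
    return prev[n2]


def mwu_exact_sf(u: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """Exact two-sided Mann-Whitney p-value(s) for statistic ``u`` (no ties).

    Uses the symmetric null: p = 2 * P(U >= max(u, n1*n2 - u)), capped at 1.
    """
    counts = _mwu_counts(n1, n2)
    total = counts.sum()
    sf = np.cumsum(counts[::-1])[::-1] / total  # P(U >= k)
    u = np.asarray(u)
    hi = np.maximum(u, n1 * n2 - u).astype(int)
    return np.minimum(2.0 * sf[hi], 1.0)


def _u_and_ties(x: np.ndarray, y: np.ndarray):
    combined = np.concatenate([x, y], axis=-1)
    ranks = sps.rankdata(combined, axis=-1)
    n1 = x.shape[-1]
    r1 = ranks[..., :n1].sum(axis=-1)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    return u1, ranks


def _tie_term_row(row: np.ndarray) -> float:
    """sum(t^3 - t) over the tie groups of one 1-D value vector."""
    _, counts = np.unique(row, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float((t**3 - t).sum())


def rank_sum_test_matrix(a: np.ndarray, b: np.ndarray, exact_max_n: int = 25):
    """Two-sided rank-sum p-values for each row of ``a`` vs the same row of ``b``.

    Exact tail when both group sizes are <= ``exact_max_n`` and the row has no
    ties; otherwise the tie-corrected, continuity-corrected normal
    approximation.  Returns ``(u_statistics, p_values)``.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    n1, n2 = a.shape[1], b.shape[1]
    u1, ranks = _u_and_ties(a, b)
    has_ties = (np.diff(np.sort(ranks, axis=-1), axis=-1) == 0).any(axis=-1)
    p = np.empty(a.shape[0])

    exact_ok = (~has_ties) & (max(n1, n2) <= exact_max_n)
    if exact_ok.any():
        p[exact_ok] = mwu_exact_sf(u1[exact_ok], n1, n2)
    approx = ~exact_ok
    if approx.any():
        tie_term = np.array(
            [_tie_term_row(ranks[i]) for i in np.flatnonzero(approx)]
        )
        n = n1 + n2
        mu = n1 * n2 / 2.0
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        var = np.maximum(var, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (np.abs(u1[approx] - mu) - 0.5) / np.sqrt(var)
        pz = 2.0 * sps.norm.sf(z)
        pz = np.where(var == 0, 1.0, np.clip(pz, 0.0, 1.0))
        p[approx] = np.minimum(pz, 1.0)
    return u1, p


def rank_sum_test(x, y, exact_max_n: int = 25) -> float:
    """Two-sided rank-sum p for two 1-D samples (see rank_sum_test_matrix)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.concatenate([x, y]).std() == 0:
        return 1.0
    _, p = rank_sum_test_matrix(x[None, :], y[None, :], exact_max_n=exact_max_n)
    return float(p[0])


def kruskal_p(*groups) -> float:
    """Kruskal-Wallis omnibus p; defined as 1.0 when all values are identical."""
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if pooled.std() == 0:
        return 1.0
    return float(sps.kruskal(*groups).pvalue)


def pairwise_rank_sum(
    groups: dict[str, np.ndarray], adjust: str = "bonferroni"
) -> dict[tuple[str, str], float]:
    """All pairwise two-sided rank-sum tests with multiplicity adjustment
    (``bonferroni`` or ``bh``) across the pairs."""
    names = list(groups)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    raw = np.array([rank_sum_test(groups[a], groups[b]) for a, b in pairs])
    if adjust == "bonferroni":
        adj = np.minimum(raw * len(pairs), 1.0)
    elif adjust == "bh":
        adj = bh_adjust(raw)
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return {pair: float(p) for pair, p in zip(pairs, adj)}


def dunn_posthoc(
    groups: dict[str, np.ndarray], adjust: str = "bonferroni"
) -> dict[tuple[str, str], float]:
    """Dunn's rank-based multiple-comparison test after Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt([N(N+1)/12 - T/(12(N-1))] (1/n_i + 1/n_j))
    with T = sum(t^3 - t) over tie groups; two-sided p, adjusted across pairs.
    """
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    pooled = np.concatenate(arrays)
    N = pooled.size
    if pooled.std() == 0:
        return {
            (a, b): 1.0 for i, a in enumerate(names) for b in names[i + 1 :]
        }
    ranks = sps.rankdata(pooled)
    tie = _tie_term_row(ranks)
    sizes = [a.size for a in arrays]
    mean_ranks = []
    pos = 0
    for n in sizes:
        mean_ranks.append(ranks[pos : pos + n].mean())
        pos += n
    var_base = N * (N + 1) / 12.0 - tie / (12.0 * (N - 1))
    pairs = [(i, j) for i in range(len(names)) for j in range(i + 1, len(names))]
    raw = []
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        raw.append(2.0 * sps.norm.sf(abs(z)))
    raw = np.array(raw)
    if adjust == "bonferroni":
        adj = np.minimum(raw * len(pairs), 1.0)
    elif adjust == "bh":
        adj = bh_adjust(np.clip(raw, np.finfo(float).tiny, 1.0))
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return {(names[i], names[j]): float(p) for (i, j), p in zip(pairs, adj)}
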