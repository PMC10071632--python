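"""Small statistical primitives shared across modules.

The exact Wilcoxon rank-sum enumeration and the vectorised chi-squared
statistic are hand-rolled because the comparisons downstream need exact
tie handling and array-of-tables evaluation; Benjamini-Hochberg is
delegated to statsmodels.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: combined group size up to which the rank-sum test enumerates exactly
EXACT_RANK_SUM_LIMIT = 16


def mann_whitney_u(x, y) -> float:
    """U statistic for group x (number of (x_i, y_j) pairs with x_i > y_j,
    ties counting 1/2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum / Mann-Whitney test.

    Exact enumeration over all C(n1+n2, n1) group assignments of the
    pooled values (correct under ties) when n1 + n2 <= 16; otherwise the
    normal approximation with tie correction.  The two-sided exact p is
    2 * min(P(U <= u), P(U >= u)), capped at 1.

    Returns (U, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("rank-sum test needs two non-empty groups")
    u_obs = mann_whitney_u(x, y)
    n = n1 + n2
    if n <= EXACT_RANK_SUM_LIMIT:
        pooled = np.concatenate([x, y])
        total = comb(n, n1)
        le = ge = 0
        idx = np.arange(n)
        for chosen in combinations(idx, n1):
            mask = np.zeros(n, dtype=bool)
            mask[list(chosen)] = True
            u = mann_whitney_u(pooled[mask], pooled[~mask])
            if u <= u_obs + 1e-12:
                le += 1
            if u >= u_obs - 1e-12:
                ge += 1
        p = min(1.0, 2.0 * min(le, ge) / total)
        return u_obs, p
    _, p = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u_obs, float(p)


def chi_squared(observed) -> tuple[np.ndarray, np.ndarray]:
    """Pearson chi-squared statistic (no continuity correction) for one
    R x C table or an array of tables shaped (..., R, C).

    Returns (statistic, p_value) with the leading shape preserved.
    Degenerate tables (a zero row or column margin) get statistic 0 and
    p 1: they carry no association information.
    """
    obs = np.asarray(observed, dtype=float)
    row = obs.sum(axis=-1, keepdims=True)
    col = obs.sum(axis=-2, keepdims=True)
    n = obs.sum(axis=(-2, -1), keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = row * col / n
        terms = (obs - expected) ** 2 / expected
    terms = np.where(expected > 0, terms, 0.0)
    stat = terms.sum(axis=(-2, -1))
    r_eff = (row.squeeze(-1) > 0).sum(axis=-1)
    c_eff = (col.squeeze(-2) > 0).sum(axis=-1)
    df = np.maximum(r_eff - 1, 0) * np.maximum(c_eff - 1, 0)
    p = np.where(df > 0, sps.chi2.sf(stat, np.maximum(df, 1)), 1.0)
    stat = np.where(df > 0, stat, 0.0)
    if np.ndim(observed) == 2:
        return float(stat), float(p)
    return stat, p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def threshold_percentile(values, q: float = 95.0) -> float:
    """Percentile used for null-score thresholds.

    Uses the exclusive-step ("higher") definition, so a value strictly
    above the returned threshold is in the top (100-q)% of the null: on
    the grid 0.00..0.99 the 95th percentile is 0.95.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty null set")
    return float(np.quantile(values, q / 100.0, method="higher"))


def ecdf(values) -> tuple[np.ndarray, np.ndarray]:
    """Sorted values and cumulative fractions (ends at 1)."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        return v, v
    frac = np.arange(1, v.size + 1) / v.size
    return v, frac
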