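"""Small shared statistics: moments, Spearman helpers, multiple-testing wrappers."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def moments(values: np.ndarray) -> np.ndarray:
    """(mean, SD, skewness, excess kurtosis) of a sample.

    SD uses the n-1 denominator; skewness is g1 = m3 / m2^1.5 and kurtosis
    is excess kurtosis g2 = m4 / m2^2 - 3 (population moment ratios, normal
    -> 0).  A zero-variance sample maps skewness and kurtosis to 0 by
    convention.  Raises on an empty sample.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("moments of an empty sample")
    mean = values.mean()
    if values.size == 1:
        return np.array([mean, 0.0, 0.0, 0.0])
    sd = values.std(ddof=1)
    if sd == 0:
        return np.array([mean, 0.0, 0.0, 0.0])
    d = values - mean
    m2 = np.mean(d**2)
    skew = np.mean(d**3) / m2**1.5
    kurt = np.mean(d**4) / m2**2 - 3.0
    return np.array([mean, sd, skew, kurt])


def spearman(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rank correlation with average-rank ties.

    Returns NaN when either vector is constant (undefined rank correlation).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.all(a == a[0]) or np.all(b == b[0]):
        return float("nan")
    ra = sps.rankdata(a)
    rb = sps.rankdata(b)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    return float(ra @ rb / np.sqrt((ra @ ra) * (rb @ rb)))


def rank_rows(x: np.ndarray) -> np.ndarray:
    """Average ranks along the last axis, row by row."""
    return sps.rankdata(x, axis=-1)


def spearman_matrix(rows: np.ndarray) -> np.ndarray:
    """All-pairs Spearman correlation between the rows of a matrix."""
    ranks = rank_rows(np.asarray(rows, dtype=float))
    sd = ranks.std(axis=1)
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(ranks)
    c[sd == 0, :] = np.nan
    c[:, sd == 0] = np.nan
    np.fill_diagonal(c, 1.0)
    return c


def _check_pvals(pvals: np.ndarray) -> np.ndarray:
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size and ((pvals < 0) | (pvals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return pvals


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR), capped at 1."""
    pvals = _check_pvals(pvals)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values (FWER), capped at 1.

    adj_(i) = max_{j <= i} (m - j + 1) * p_(j) over the sorted p-values.
    """
    pvals = _check_pvals(pvals)
    if pvals.size == 0:
        return pvals
    m = pvals.size
    order = np.argsort(pvals, kind="stable")
    stepped = (m - np.arange(m)) * pvals[order]
    adj = np.minimum(np.maximum.accumulate(stepped), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def adjusted_r2(r2: float, n: int, n_predictors: int = 1) -> float:
    """R-squared penalized for model degrees of freedom."""
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_predictors - 1)
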