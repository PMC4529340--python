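"""Clinic-pathological statistics: contingency tests, Cohen's kappa,
partial correlation, and the percentage/ratio arithmetic of cohort tables.

2x2 chi-square applies the Yates continuity correction by default (this is
the convention that reproduces the published cohort-table p-values);
Fisher's exact two-sided p sums the probabilities of all tables no more
probable than the observed one.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .datasets import TranscohortError
from .subtypes import round_half_up_pct

__all__ = [
    "chi_square_test",
    "fisher_exact",
    "cohens_kappa",
    "partial_correlation",
    "percentage_and_ratio",
]


def _as_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise TranscohortError("contingency table must be at least 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise TranscohortError("table entries must be non-negative integers")
    return t


def chi_square_test(table, continuity_correction: bool = True):
    """Pearson chi-square test of independence; Yates correction for 2x2.

    Returns (statistic, df, p).  The correction flag only applies to 2x2
    tables (larger tables are never corrected).
    """
    t = _as_table(table)
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        raise TranscohortError("zero marginal total; expected counts undefined")
    correction = continuity_correction and t.shape == (2, 2)
    stat, p, df, _ = stats.chi2_contingency(t, correction=correction)
    return float(stat), int(df), float(p)


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Sums the hypergeometric probabilities of every table with the same
    margins whose probability does not exceed the observed table's.
    """
    t = _as_table(table)
    if t.shape != (2, 2):
        raise TranscohortError("Fisher's exact test requires a 2x2 table")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def cohens_kappa(table) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e)."""
    t = _as_table(table)
    if t.shape[0] != t.shape[1]:
        raise TranscohortError("kappa requires a square table")
    n = t.sum()
    if n == 0:
        raise TranscohortError("empty table")
    p_o = np.trace(t) / n
    p_e = float((t.sum(axis=1) / n) @ (t.sum(axis=0) / n))
    if abs(1.0 - p_e) < 1e-15:
        raise TranscohortError("degenerate margins: chance agreement is 1")
    return float((p_o - p_e) / (1.0 - p_e))


def partial_correlation(x, y, covariates=None):
    """Correlation of x and y after regressing out the covariates.

    Residualizes both variables on the covariate matrix (with intercept) and
    returns the Pearson correlation of the residuals with a t-based p at
    n - n_covariates - 2 degrees of freedom.  With no covariates this is the
    plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if covariates is None:
        Z = np.ones((n, 1))
        k = 0
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        k = C.shape[1]
        Z = np.column_stack([np.ones(n), C])
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise TranscohortError("collinear covariates; residualization undefined")
    if n <= k + 2:
        raise TranscohortError("need n > n_covariates + 2")
    H = Z @ np.linalg.pinv(Z)
    rx = x - H @ x
    ry = y - H @ y
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        raise TranscohortError("zero residual variance")
    r = float((rx @ ry) / denom)
    r = max(-1.0, min(1.0, r))
    df = n - k - 2
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


def percentage_and_ratio(counts, total: int):
    """Round-half-up integer percentages and their pairwise ratio.

    ``counts`` may be a single count (returns one percentage) or a pair
    (numerator, denominator counts for the ratio of rounded percentages, to
    two decimals, NaN when the denominator percentage rounds to zero).
    """
    if total <= 0:
        raise TranscohortError("total must be positive")
    if np.isscalar(counts):
        return round_half_up_pct(int(counts), total)
    pcts = [round_half_up_pct(int(c), total) for c in counts]
    if len(pcts) == 2:
        ratio = round(pcts[0] / pcts[1], 2) if pcts[1] > 0 else float("nan")
        return pcts, ratio
    return pcts, float("nan")
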