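"""Shared statistical primitives.

Thin, validated wrappers around scipy / statsmodels with the degenerate-case
conventions the pipeline relies on (zero-variance Welch inputs, empty
p-value vectors, asymptotic two-sample KS p-values).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["welch_t", "bh_fdr", "ks_test", "fisher_exact"]


def welch_t(x, y) -> tuple[float, float]:
    """Welch's two-sample t test (unequal variances, Satterthwaite df).

    Returns ``(t, p)`` with ``t > 0`` when ``mean(x) > mean(y)`` and a
    two-sided p-value.  Both groups need at least two observations.  If both
    groups have zero variance the test is degenerate: equal means give
    ``(0.0, 1.0)``, unequal means give ``(±inf, 0.0)`` with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t needs >= 2 observations per group")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        warnings.warn("welch_t: both groups constant with unequal means", stacklevel=2)
        return float(np.sign(x.mean() - y.mean()) * np.inf), 0.0
    t, p = sps.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_fdr expects a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ks_test(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test.

    ``D = sup |ECDF_x - ECDF_y|`` with the asymptotic p-value (only FDR
    ranks matter downstream, so the exact small-sample distribution is not
    needed).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("ks_test needs non-empty samples")
    res = sps.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 contingency table.

    Sums hypergeometric probabilities of tables at most as probable as the
    observed one, holding the margins fixed.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("fisher_exact expects a 2x2 table")
    if np.any(t < 0):
        raise ValueError("fisher_exact: negative entries")
    if not np.allclose(t, np.round(t)):
        raise ValueError("fisher_exact: non-integer entries")
    if t.sum() == 0:
        raise ValueError("fisher_exact: empty table")
    return float(sps.fisher_exact(t.astype(int), alternative="two-sided")[1])
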