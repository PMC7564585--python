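"""Shared statistical primitives: pooled t-test and Benjamini-Hochberg.

Kept in one place so the control-vs-treatment comparison and the same-same
permutation analysis use exactly the same test flavour (two-sided Students
t-test with pooled variance, on the lnNSAF scale).
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["ttest_rows", "ttest_shared", "bh_adjust"]


def ttest_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise two-sided pooled-variance t-test p-values.

    Degenerate rows (zero pooled variance) carry no distributional
    information: equal means give p = 1, unequal means the p -> 0 limit.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need at least 2 replicates per group")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in t-test input")
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.ttest_ind(a, b, axis=1, equal_var=True).pvalue
    p = np.array(p, dtype=float, copy=True)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        equal = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = 0.0
    return p


def ttest_shared(ln_nsaf_control, ln_nsaf_treatment) -> float:
    """Students t-test p-value for one shared protein's lnNSAF vectors."""
    a = np.asarray(ln_nsaf_control, dtype=float)[None, :]
    b = np.asarray(ln_nsaf_treatment, dtype=float)[None, :]
    return float(ttest_rows(a, b)[0])


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (Q values).

    q_(i) = min_{j >= i} ( m * p_(j) / j ), clipped at 1; monotone in p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
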