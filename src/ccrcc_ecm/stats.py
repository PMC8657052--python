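"""Shared statistical kernels.

Thin wrappers over scipy/statsmodels with explicit handling of the
degenerate cases that show up in small-replicate assay data (identical
groups, zero variance).  Kept in one place so every module reports the
same t statistics and the same multiple-testing correction.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def welch_t(x, y) -> tuple[float, float]:
    """Welch's unequal-variance two-sample t-test.

    Returns ``(t, p)`` with the two-sided p-value.  Each sample needs at
    least two observations.  If both samples are constant and share the
    same mean the test is defined as (0, 1): there is no evidence of a
    difference, rather than an indeterminate 0/0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t requires at least 2 observations per sample")
    if np.var(x, ddof=1) == 0.0 and np.var(y, ddof=1) == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return float(np.sign(x.mean() - y.mean()) * np.inf), 0.0
    t, p = sps.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def student_t(x, y) -> tuple[float, float]:
    """Classic pooled-variance Student's t-test (two-sided)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("student_t requires at least 2 observations per sample")
    if np.var(x, ddof=1) == 0.0 and np.var(y, ddof=1) == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return float(np.sign(x.mean() - y.mean()) * np.inf), 0.0
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values).

    NaN entries are passed through as NaN and do not count toward the
    number of tests.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q
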