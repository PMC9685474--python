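"""Classical tests shared by the attribution and projection stages.

Thin, validated wrappers around :mod:`scipy.stats`: a paired t-test on
daily rate differences, a Pearson chi-square on the 2x2 hot-day table, and
one-way ANOVA across projection periods.  The wrappers add the degenerate-
case handling the pipeline needs (zero-variance differences, empty table
margins) and return plain named tuples.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import stats

__all__ = ["PairedT", "ChiSquare", "Anova", "paired_t", "hot_day_chisq", "one_way_anova"]


class PairedT(NamedTuple):
    statistic: float
    df: int
    pvalue: float
    mean_diff: float
    degenerate: bool = False


class ChiSquare(NamedTuple):
    statistic: float
    df: int
    pvalue: float
    table: np.ndarray  # rows: (factual, counterfactual); cols: (hot, not hot)


class Anova(NamedTuple):
    statistic: float
    df_between: int
    df_within: int
    pvalue: float


def paired_t(a, b) -> PairedT:
    """Two-sided paired t-test on day-wise differences ``a - b``.

    Zero-variance differences (all days shifted by the same amount) are a
    degenerate case: reported with ``degenerate=True`` and a p-value of 1
    when the common difference is zero, 0 otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired t-test needs two aligned 1-d series")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    md = float(d.mean())
    if np.allclose(d.std(ddof=1), 0.0):
        if md == 0.0:
            return PairedT(0.0, n - 1, 1.0, 0.0, degenerate=True)
        return PairedT(float(np.sign(md)) * np.inf, n - 1, 0.0, md, degenerate=True)
    r = stats.ttest_rel(a, b)
    return PairedT(float(r.statistic), n - 1, float(r.pvalue), md)


def hot_day_chisq(
    tmax_factual, tmax_counterfactual, threshold: float = 30.0, correction: bool = False
) -> ChiSquare:
    """Pearson chi-square comparing hot-day frequency between two series.

    A hot day has daily maximum temperature at or above ``threshold``
    (default 30 °C).  Continuity correction is off by default (large daily
    samples); enable with ``correction=True``.
    """
    tf = np.asarray(tmax_factual, dtype=float)
    tc = np.asarray(tmax_counterfactual, dtype=float)
    if tf.size == 0 or tc.size == 0:
        raise ValueError("both series must be non-empty")
    table = np.array(
        [
            [np.sum(tf >= threshold), np.sum(tf < threshold)],
            [np.sum(tc >= threshold), np.sum(tc < threshold)],
        ],
        dtype=float,
    )
    col = table.sum(axis=0)
    row = table.sum(axis=1)
    if np.any(col == 0):
        which = "hot" if col[0] == 0 else "not-hot"
        raise ValueError(f"degenerate 2x2 table: the {which} margin is empty")
    if np.any(row == 0):
        raise ValueError("degenerate 2x2 table: an empty series margin")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=correction)
    return ChiSquare(float(chi2), int(df), float(p), table.astype(int))


def one_way_anova(*groups) -> Anova:
    """One-way ANOVA across two or more groups of daily rates."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    gs = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in gs):
        raise ValueError("every group needs at least 2 observations")
    r = stats.f_oneway(*gs)
    k = len(gs)
    n = sum(g.size for g in gs)
    return Anova(float(r.statistic), k - 1, n - k, float(r.pvalue))
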