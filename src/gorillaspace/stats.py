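"""Exact nonparametric statistics for paired range-overlap comparisons.

The exact Wilcoxon signed-rank test enumerates all 2^n assignments of signs
to the ranked absolute differences, so p-values are exact even with midranks
for ties — matching the behaviour of exact rank-test implementations used
for small paired samples (here: one pair of overlap percentages per group).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

__all__ = ["wilcoxon_signed_rank_exact", "median_range", "count_below"]

_MAX_EXACT_N = 40  # the exact null distribution is computed by convolution


def _exact_null_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Counts of each value of 2*T+ over all 2^n sign assignments.

    ``ranks2`` are the midranks doubled, hence integers, so the null
    distribution lives on 0..sum(ranks2) and builds up by convolution: each
    rank either joins the positive set (shifting the distribution) or not.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank_exact(x, y):
    """Exact two-tailed Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped; tied absolute differences receive
    midranks.  T+ is the sum of ranks of the positive differences; its exact
    null distribution over all 2^n sign assignments of the ranks is computed
    by convolution.  The two-tailed p doubles the smaller exact tail
    probability (capped at 1), with both tails inclusive of the observed
    statistic.

    Returns
    -------
    (T_plus, p_two_tailed, n_used)
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero; test undefined")
    if n > _MAX_EXACT_N:
        raise ValueError(f"exact test limited to n <= {_MAX_EXACT_N}")
    ranks = rankdata(np.abs(d))
    t_plus = float(ranks[d > 0].sum())
    ranks2 = np.round(2.0 * ranks).astype(int)  # midranks doubled -> integers
    counts = _exact_null_distribution(ranks2)
    denom = counts.sum()  # 2^n
    t2 = int(round(2.0 * t_plus))
    ge = counts[t2:].sum() / denom
    le = counts[:t2 + 1].sum() / denom
    p = min(1.0, 2.0 * min(ge, le))
    return t_plus, float(p), n


def median_range(values):
    """Sample median (mean of middle two for even n), minimum and maximum."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("median of empty sample is undefined")
    return float(np.median(v)), float(v.min()), float(v.max())


def count_below(values, threshold: float) -> int:
    """Number of values strictly below the threshold."""
    v = np.asarray(values, dtype=float)
    return int(np.sum(v < threshold))
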