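"""Independent oracles used by the test suite.

Everything here is implemented from first principles (enumeration, hand
formulas) and deliberately shares no code with the package.
"""

from fractions import Fraction
from math import comb

import numpy as np


def fisher_two_sided_exact(table) -> Fraction:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Sums P(table') over all tables with the observed margins whose
    probability does not exceed the observed table's.
    """
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(x: int) -> Fraction:
        return Fraction(comb(row1, x) * comb(row2, col1 - x), comb(n, col1))

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        px = prob(x)
        if px <= p_obs:
            total += px
    return total


def kruskal_wallis_hand(*groups):
    """Tie-corrected KW H from the rank formula, written independently."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    n = len(pooled)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    i = 0
    sorted_vals = pooled[order]
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    h = 0.0
    start = 0
    for g in groups:
        m = len(g)
        r = ranks[start : start + m].sum()
        h += r * r / m
        start += m
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1 - (counts**3 - counts).sum() / (n**3 - n)
    return h / correction


def bh_stepup(pvals):
    """Textbook Benjamini-Hochberg adjusted p-values (step-up)."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = p[i] * m / rank_from_top
        running_min = min(running_min, val)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


def average_ranks(values):
    values = np.asarray(values, float)
    n = len(values)
    ranks = np.empty(n)
    for i, v in enumerate(values):
        less = np.sum(values < v)
        equal = np.sum(values == v)
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def spearman_hand(x, y):
    """Spearman rho as Pearson correlation of average ranks."""
    rx, ry = average_ranks(x), average_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def rank_sum_normal_p(a, b):
    """Wilcoxon rank-sum two-sided p via the normal approximation
    (no ties, no continuity correction)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = average_ranks(pooled)
    w = ranks[:n1].sum()
    mean = n1 * (n1 + n2 + 1) / 2.0
    sd = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    from math import erf, sqrt

    z = abs(w - mean) / sd
    return 2 * (1 - 0.5 * (1 + erf(z / sqrt(2))))


def filter_decisions_bruteforce(levels, known_flags, min_level, min_samples):
    """Exhaustive re-derivation of the high-confidence filter for a small
    level matrix (rows = sites, NaN = missing)."""
    decisions = []
    for row, known in zip(levels, known_flags):
        n_above = sum(1 for v in row if not np.isnan(v) and v >= min_level)
        decisions.append(n_above >= min_samples or bool(known))
    return decisions
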