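"""Independently coded brute-force oracles used by the test suite.

These deliberately avoid the package's implementation paths (and scipy's
shortcuts where the point is to cross-check them): plain loops, explicit
sorting, and exhaustive enumeration.
"""

from itertools import combinations
from math import floor, log2


def _quantile75(values):
    """75th percentile with linear interpolation (matches the convention the
    reference-library picker uses)."""
    vals = sorted(values)
    pos = 0.75 * (len(vals) - 1)
    lo = int(pos)
    frac = pos - lo
    if lo + 1 < len(vals):
        return vals[lo] * (1 - frac) + vals[lo + 1] * frac
    return vals[lo]


def _average_ranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1  # ranks are 1-based
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def tmm_factors_oracle(counts, logratio_trim=0.30, abundance_trim=0.05):
    """Step-by-step TMM normalization factors for a genes x samples table.

    Explicit M/A lists, double trimming by average ranks, and the
    inverse-variance weighted mean, followed by rescaling to geometric
    mean 1.
    """
    n_genes = len(counts)
    n_samples = len(counts[0])
    libsize = [sum(counts[g][s] for g in range(n_genes))
               for s in range(n_samples)]
    f75 = [_quantile75([counts[g][s] / libsize[s] for g in range(n_genes)])
           for s in range(n_samples)]
    mean_f75 = sum(f75) / n_samples
    ref = min(range(n_samples), key=lambda s: abs(f75[s] - mean_f75))

    factors = []
    for s in range(n_samples):
        ms, avals, ws = [], [], []
        for g in range(n_genes):
            y, r = counts[g][s], counts[g][ref]
            if y > 0 and r > 0:
                ms.append(log2((y / libsize[s]) / (r / libsize[ref])))
                avals.append(0.5 * log2((y / libsize[s]) * (r / libsize[ref])))
                ws.append((libsize[s] - y) / (libsize[s] * y)
                          + (libsize[ref] - r) / (libsize[ref] * r))
        if not ms:
            raise ValueError("no shared positive genes")
        n = len(ms)
        lo_m = floor(n * logratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = floor(n * abundance_trim) + 1
        hi_a = n + 1 - lo_a
        rank_m = _average_ranks(ms)
        rank_a = _average_ranks(avals)
        num = den = 0.0
        for i in range(n):
            if lo_m <= rank_m[i] <= hi_m and lo_a <= rank_a[i] <= hi_a:
                num += ms[i] / ws[i]
                den += 1.0 / ws[i]
        factors.append(2.0 ** (num / den) if den > 0 else 1.0)

    log_mean = sum(log2(f) for f in factors) / n_samples
    return [f / 2.0 ** log_mean for f in factors]


def ranksum_exact_p(a, b, alternative="two-sided"):
    """Exact Mann-Whitney p-value by enumerating every label assignment.

    Valid for tie-free pooled data; counts assignments whose U statistic is
    at least (greater) / at most (less) as extreme as observed.
    """
    pooled = list(a) + list(b)
    n_a = len(a)

    def u_stat(idx_a):
        xs = [pooled[i] for i in idx_a]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx_a]
        return sum(1 for x in xs for y in ys if x > y)

    observed = u_stat(set(range(n_a)))
    us = [u_stat(set(c)) for c in combinations(range(len(pooled)), n_a)]
    total = len(us)
    if alternative == "greater":
        return sum(u >= observed for u in us) / total
    if alternative == "less":
        return sum(u <= observed for u in us) / total
    mean_u = n_a * (len(pooled) - n_a) / 2
    dev = abs(observed - mean_u)
    return min(1.0, sum(abs(u - mean_u) >= dev for u in us) / total)


def bh_stepup_oracle(pvalues):
    """Benjamini-Hochberg adjusted p-values by the literal step-up rule."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(1.0, pvalues[i] * m / rank_from_top)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted
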