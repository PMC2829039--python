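"""Independent oracles shared by unit and acceptance tests.

Everything here is deliberately brute-force (enumeration, direct formulas)
and independent of the implementation paths it is used to check.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def ecdf_d_statistic(a, b) -> float:
    """Two-sample KS D via direct ECDF comparison at pooled values."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    ts = np.union1d(a, b)
    fa = np.searchsorted(a, ts, side="right") / a.size
    fb = np.searchsorted(b, ts, side="right") / b.size
    return float(np.abs(fa - fb).max())


def ks_pvalue_enumeration(a, b) -> float:
    """Exact two-sample KS p-value by enumerating all interleavings.

    Under the continuous null every interleaving of the n 'a' observations
    and m 'b' observations is equally likely; the p-value is the fraction of
    interleavings whose path deviation max |i/n - j/m| is >= the observed D.
    """
    n, m = len(a), len(b)
    d_obs = ecdf_d_statistic(a, b)
    total = comb(n + m, n)
    hits = 0
    for positions in itertools.combinations(range(n + m), n):
        i = j = 0
        d = 0.0
        pos = set(positions)
        for step in range(n + m):
            if step in pos:
                i += 1
            else:
                j += 1
            d = max(d, abs(i / n - j / m))
        if d >= d_obs - 1e-12:
            hits += 1
    return hits / total


def permutation_pvalue_exhaustive(x, y) -> float:
    """Sign-taxonomy permutation p-value over all n! feature permutations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def pearson(u, v):
        return float(np.corrcoef(u, v)[0, 1])

    r_obs = pearson(x, y)
    rs = [pearson(x, np.asarray(p)) for p in itertools.permutations(y)]
    rs = np.array(rs)
    if r_obs >= 0:
        return float(np.mean(rs >= r_obs))
    return float(np.mean(rs <= r_obs))


def bh_stepup(p) -> np.ndarray:
    """Direct Benjamini-Hochberg step-up computation."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
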