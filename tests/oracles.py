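"""Independent brute-force oracles used only by the test suite.

Everything here is deliberately written as plain loops over the textbook
formulas, sharing no code with the package, so that agreement between the
two routes is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


def naive_km(times, events):
    """Product-limit estimate via an explicit loop: [(t, S(t)), ...]."""
    pairs = sorted(zip(times, events))
    out = []
    s = 1.0
    distinct = sorted({t for t, e in pairs if e == 1})
    for t in distinct:
        n_at_risk = sum(1 for ti, _ in pairs if ti >= t)
        deaths = sum(1 for ti, ei in pairs if ti == t and ei == 1)
        s *= 1.0 - deaths / n_at_risk
        out.append((t, s))
    return out


def naive_logrank_chi(times_a, events_a, times_b, events_b):
    """Two-group log-rank chi-square via explicit loops over event times."""
    a = list(zip(times_a, events_a))
    b = list(zip(times_b, events_b))
    pooled = sorted({t for t, e in a + b if e == 1})
    u = 0.0
    v = 0.0
    for t in pooled:
        n1 = sum(1 for ti, _ in a if ti >= t)
        n2 = sum(1 for ti, _ in b if ti >= t)
        n = n1 + n2
        d1 = sum(1 for ti, ei in a if ti == t and ei == 1)
        d2 = sum(1 for ti, ei in b if ti == t and ei == 1)
        d = d1 + d2
        if n == 0:
            continue
        u += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return u * u / v if v > 0 else float("nan")


def naive_bh(pvalues):
    """O(m^2) Benjamini-Hochberg step-up adjustment."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [None] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(1.0, p[i] * m / rank_from_top)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def pearson_direct(x, y):
    """Pearson r from the covariance formula, no library calls."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def exhaustive_rescan(values, times, events, positions, sig=None):
    """Re-scan every cut position with the naive log-rank; return
    {rank: p} for usable cuts (independent reconstruction of the scan)."""
    from scipy.stats import chi2

    order = np.lexsort((np.arange(len(values)), np.asarray(values, float)))
    sv = np.asarray(values, float)[order]
    st = np.asarray(times, float)[order]
    se = np.asarray(events, int)[order]
    out = {}
    for k in positions:
        if sv[k - 1] == sv[k]:
            continue
        ta, ea = st[:k], se[:k]
        tb, eb = st[k:], se[k:]
        if ea.sum() == 0 or eb.sum() == 0:
            continue
        chi = naive_logrank_chi(ta, ea, tb, eb)
        if not math.isfinite(chi):
            continue
        out[int(k)] = float(chi2.sf(chi, 1))
    return out
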