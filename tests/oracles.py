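"""Independent textbook-formula oracles used to cross-check the
implementation. Deliberately hand-coded from the classical formulas
(pooled two-sample t, Welch t with Welch–Satterthwaite df, variance-
ratio F) and kept free of the code paths they verify: only distribution
CDFs come from scipy, never the test statistics."""

import math

import numpy as np
from scipy import stats


def oracle_pooled_t(a, b):
    """Pooled-variance two-sample t-test: (t, df, two-sided p)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    se = math.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    if se == 0:
        return 0.0, float(df), 1.0
    t = (a.mean() - b.mean()) / se
    p = 2 * stats.t.sf(abs(t), df)
    return t, float(df), p


def oracle_welch_t(a, b):
    """Welch unequal-variance t-test: (t, Welch–Satterthwaite df, p)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
    se = math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (na - 1) + vb ** 2 / (nb - 1))
    t = (a.mean() - b.mean()) / se
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


def oracle_f_test(a, b):
    """Two-sided variance-ratio F-test, larger variance on top: (F, p)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va >= vb:
        f, dfn, dfd = va / vb, len(a) - 1, len(b) - 1
    else:
        f, dfn, dfd = vb / va, len(b) - 1, len(a) - 1
    p = min(1.0, 2 * (1.0 - stats.f.cdf(f, dfn, dfd)))
    return f, p


def oracle_venn_regions(named_sets):
    """Exhaustive per-element membership enumeration of Venn regions."""
    labels = list(named_sets)
    universe = set().union(*named_sets.values())
    regions = {}
    from itertools import combinations

    for k in range(1, len(labels) + 1):
        for combo in combinations(labels, k):
            regions[frozenset(combo)] = set()
    for el in universe:
        membership = frozenset(l for l in labels if el in named_sets[l])
        regions[membership].add(el)
    return regions
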