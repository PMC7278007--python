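"""Independent brute-force oracles shared by the test modules."""

import itertools

import numpy as np


def wilcoxon_enumeration(diffs):
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns
    (untied, non-zero differences only)."""
    d = np.asarray(diffs, float)
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    ws = np.array([
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ])
    total = 2.0**n
    p = 2.0 * min((ws <= w_obs).sum(), (ws >= w_obs).sum()) / total
    return min(p, 1.0)


def mann_whitney_enumeration(a, b):
    """Exact two-sided Mann–Whitney p by enumerating all C(n, na) group
    assignments of the pooled (untied) sample."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    na = len(a)

    def u_stat(idx_a):
        xa = pooled[list(idx_a)]
        xb = np.delete(pooled, list(idx_a))
        return (xa[:, None] > xb[None, :]).sum()

    u_obs = (a[:, None] > b[None, :]).sum()
    us = np.array([u_stat(c) for c in itertools.combinations(range(len(pooled)), na)])
    p = 2.0 * min((us <= u_obs).sum(), (us >= u_obs).sum()) / len(us)
    return min(p, 1.0)


def quantile_oracle(values, fraction):
    """Interpolated order statistic at cumulative fraction from the bottom."""
    v = np.sort(np.asarray(values, float))
    pos = fraction * (len(v) - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (pos - lo) * (v[hi] - v[lo])
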