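"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from nemasleep.synthetic import transient_kernel


def rle_runs(values, target):
    """Run-length-encoding oracle: maximal runs of `target` as (start, end)."""
    runs, start = [], None
    for i, v in enumerate(values):
        if v == target and start is None:
            start = i
        elif v != target and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(values)))
    return runs


def exact_ranksum_oracle(x, y):
    """Exhaustive-enumeration Wilcoxon rank-sum (tie-free samples only).

    Enumerates every assignment of the pooled ranks to the first group and
    returns (rank sum of x, two-sided p) with p = 2 * min(P(W <= w),
    P(W >= w)) capped at 1.
    """
    from itertools import combinations

    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    n, m = len(x) + len(y), len(x)
    all_ranks = range(1, n + 1)
    dist = [sum(c) for c in combinations(all_ranks, m)]
    total = len(dist)
    p_le = sum(1 for w in dist if w <= w_obs) / total
    p_ge = sum(1 for w in dist if w >= w_obs) / total
    return w_obs, min(1.0, 2 * min(p_le, p_ge))


def fisher_oracle(table):
    """Brute-force two-sided Fisher p by hypergeometric enumeration."""
    from math import comb

    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    denom = comb(n, col1)

    def prob(k):
        if k < 0 or k > row1 or col1 - k < 0 or col1 - k > row2:
            return 0.0
        return comb(row1, k) * comb(row2, col1 - k) / denom

    p_obs = prob(a)
    return sum(p for k in range(col1 + 1)
               if (p := prob(k)) <= p_obs * (1 + 1e-9))


def otsu_bruteforce(pixels):
    """Exhaustive-search Otsu threshold: maximize between-class variance."""
    values = np.unique(pixels)
    best_t, best_v = values[0], -1.0
    for t in values[:-1]:
        lo, hi = pixels[pixels <= t], pixels[pixels > t]
        if lo.size == 0 or hi.size == 0:
            continue
        v = lo.size * hi.size * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


def spaced_events(rng, n_events, lo, hi, min_gap):
    """Random event positions in [lo, hi) with guaranteed minimum spacing."""
    slack = hi - lo - (n_events - 1) * min_gap
    assert slack > 0
    offsets = np.sort(rng.integers(0, slack, n_events))
    return lo + offsets + np.arange(n_events) * min_gap


def synthetic_ratio_trace(rng, n=3000, k=8, baseline=0.4, amplitude=0.1,
                          noise_sd=0.02, rise=5.0, decay=30.0, min_gap=300):
    """1-D ratio trace with k well-separated transients; returns (trace, onsets)."""
    onsets = spaced_events(rng, k, 150, n - 300, min_gap)
    t = np.arange(n, dtype=float)
    trace = np.full(n, baseline)
    for s in onsets:
        trace += amplitude * transient_kernel(t - s, rise, decay)
    if noise_sd > 0:
        trace += rng.normal(0.0, noise_sd, n)
    return trace, onsets


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
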