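"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (explicit loops, enumeration) of the
statistical primitives, kept separate from the package code paths they
check.
"""

import itertools
import math

import numpy as np


def binomial_upper_tail(k: int, x: int, p: float = 0.5) -> float:
    """P(X >= x), X ~ Binomial(k, p), by direct summation."""
    return sum(
        math.comb(k, i) * p**i * (1 - p) ** (k - i) for i in range(x, k + 1)
    )


def hypergeom_upper_tail(x: int, N: int, K: int, n: int) -> float:
    """P(X >= x), X ~ Hypergeometric(N, K, n), by direct summation."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i) / total
        for i in range(x, min(K, n) + 1)
        if n - i <= N - K
    )


def hypergeom_upper_tail_enumerated(x: int, N: int, K: int, n: int) -> float:
    """Same tail by exhaustively enumerating all C(N, n) draws."""
    hits = 0
    total = 0
    successes = set(range(K))
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(successes.intersection(draw)) >= x:
            hits += 1
    return hits / total


def bh_stepup(pvalues):
    """Benjamini–Hochberg step-up from its textbook definition."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, m * p[i] / rank)
        q[i] = val
        prev = val
    return q


def sam_brute_force(X, y, positive_label, s0, fdr):
    """SAM two-class significance, fully enumerated, explicit loops.

    Returns (d, significant_mask, delta).  Mirrors the definition: d =
    (mean1-mean2)/(s+s0) with pooled standard error; expected order
    statistics from all distinct label assignments; symmetric band at
    the smallest delta whose estimated FDR (mean permutation count
    beyond the cut points over observed calls) is at or below fdr.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    n = X.shape[0]
    idx1 = [i for i in range(n) if y[i] == positive_label]
    n1 = len(idx1)

    def dstat(indices1):
        set1 = set(indices1)
        a = X[[i for i in range(n) if i in set1]]
        b = X[[i for i in range(n) if i not in set1]]
        r = a.mean(axis=0) - b.mean(axis=0)
        ss = ((a - a.mean(axis=0)) ** 2).sum(axis=0) + ((b - b.mean(axis=0)) ** 2).sum(axis=0)
        s = np.sqrt((1 / a.shape[0] + 1 / b.shape[0]) * ss / (n - 2))
        return r / (s + s0)

    d = dstat(idx1)
    perms = [dstat(c) for c in itertools.combinations(range(n), n1)]
    perm_sorted = [np.sort(pd) for pd in perms]
    d_bar = np.mean(perm_sorted, axis=0)
    d_sorted = np.sort(d)
    dev = d_sorted - d_bar

    def evaluate(delta):
        cut_up = math.inf
        for i in range(len(d_sorted)):
            if dev[i] >= delta and d_sorted[i] >= 0:
                cut_up = d_sorted[i]
                break
        cut_low = -math.inf
        for i in range(len(d_sorted) - 1, -1, -1):
            if dev[i] <= -delta and d_sorted[i] <= 0:
                cut_low = d_sorted[i]
                break
        called = (d >= cut_up) | (d <= cut_low)
        false_counts = [
            int(((pd >= cut_up) | (pd <= cut_low)).sum()) for pd in perms
        ]
        false = float(np.mean(false_counts))
        return called, false

    grid = sorted(set([0.0] + [abs(v) for v in dev]))
    for delta in grid:
        called, false = evaluate(delta)
        n_called = int(called.sum())
        if n_called == 0 or false / n_called <= fdr:
            return d, called, delta
    return d, np.zeros(len(d), bool), math.inf
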