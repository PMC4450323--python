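"""Independent brute-force oracles used only by the test suite.

Each oracle is implemented from first principles (log-factorials, exhaustive
enumeration, quadratic scans) and shares no code path with the package.
"""

from __future__ import annotations

import itertools
from math import exp, inf, lgamma

import numpy as np


def _log_choose(n: int, k: int) -> float:
    if k < 0 or k > n:
        return -inf
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def fisher_exact_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration.

    Sums P(table) over all tables with the observed margins whose
    probability is <= the observed table's (within a relative tolerance
    for float round-off).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = _log_choose(n, c1)

    def log_p(x: int) -> float:
        return _log_choose(r1, x) + _log_choose(r2, c1 - x) - denom

    lp_obs = log_p(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        lp = log_p(x)
        if lp <= lp_obs + 1e-9:
            total += exp(lp)
    return min(total, 1.0)


def signed_rank_enum(diffs) -> float:
    """Two-sided exact signed-rank p by enumerating all 2^n sign flips.

    Assumes non-zero differences with distinct magnitudes.  The two-sided
    p-value is P(|W+ - mu| >= |w+ - mu|) under the symmetric null.
    """
    d = np.asarray(diffs, dtype=float)
    assert (d != 0).all()
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = float(sum(r for r, s in zip(ranks, signs) if s))
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / 2 ** n


def hypergeom_tail_sum(N: int, K: int, n: int, x: int) -> float:
    """Upper-tail P(X >= x) for X ~ Hypergeom(N, K, n) by direct summation."""
    denom = _log_choose(N, n)
    total = 0.0
    for k in range(x, min(K, n) + 1):
        total += exp(_log_choose(K, k) + _log_choose(N - K, n - k) - denom)
    return min(total, 1.0)


def window_overlap_quadratic(positions, chroms, peaks, half: int):
    """All-pairs window/peak intersection check (0-based half-open window
    [pos-1-half, pos-1+half+1) vs each peak)."""
    flags = []
    peak_list = list(peaks.itertuples(index=False))
    for pos, chrom in zip(positions, chroms):
        lo, hi = pos - 1 - half, pos - 1 + half + 1
        hit = any(str(pk.chrom) == str(chrom) and pk.start < hi and lo < pk.end
                  for pk in peak_list)
        flags.append(hit)
    return flags


def bh_stepup(p):
    """Hand implementation of the Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = running
    return q
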