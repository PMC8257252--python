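"""Brute-force reference implementations used only as test oracles.

Each oracle enumerates the relevant combinatorial space directly
(itertools over sign assignments or label bijections) and is deliberately
independent of the package's vectorized / dynamic-programming code paths.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import rankdata


def _plain_t(x: np.ndarray) -> float:
    n = x.size
    mean = x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        return 0.0 if mean == 0 else np.sign(mean) * np.inf
    return mean / (sd / np.sqrt(n))


def exhaustive_signflip_p(x: np.ndarray) -> float:
    """Two-sided sign-flip p by explicit enumeration of all 2^n flips."""
    x = np.asarray(x, dtype=float)
    t_obs = abs(_plain_t(x))
    count = 0
    for signs in itertools.product((-1.0, 1.0), repeat=x.size):
        if abs(_plain_t(np.asarray(signs) * x)) >= t_obs:
            count += 1
    return count / 2.0 ** x.size


def brute_wilcoxon_p(diffs: np.ndarray) -> float:
    """Exact two-sided signed-rank p over all 2^n sign assignments.

    Zero differences must already be removed.  Mid-ranks are used for
    tied |d|; the two-sided p is the null probability of a W+ deviating
    from n(n+1)/4 at least as much as observed.
    """
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.size
    ranks = rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    mu = n * (n + 1) / 4.0
    dev = abs(w_obs - mu)
    count = 0
    for signs in itertools.product((False, True), repeat=n):
        w = ranks[np.asarray(signs)].sum()
        if abs(w - mu) >= dev - 1e-12:
            count += 1
    return count / 2.0**n


def brute_match_overlap(a: np.ndarray, b: np.ndarray, k: int) -> float:
    """Maximum label-bijection co-occurrence over all k! permutations."""
    best = 0
    for perm in itertools.permutations(range(1, k + 1)):
        total = sum(
            np.sum((a == lab) & (b == perm[lab - 1])) for lab in range(1, k + 1)
        )
        best = max(best, total)
    return best / a.size


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Hand-rolled Benjamini–Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q
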