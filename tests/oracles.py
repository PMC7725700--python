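"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: structure
scores come from exhaustive enumeration of every nested structure, and the
parsimony probability from summing the per-site Poisson series with the
per-event Jukes-Cantor difference probability.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import poisson

PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
WEIGHT = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "U"): 2, ("U", "A"): 2,
    ("G", "U"): 1, ("U", "G"): 1,
}


def best_score_exhaustive(seq: str, min_loop: int = 3, stacking: int = 1) -> int:
    """Maximum structure score by exhaustive enumeration (no memoization).

    Explores every nested structure of ``seq``: position i is left unpaired
    or paired with every admissible k; a pair spanning exactly an enclosing
    pair's interior collects the stacking bonus.
    """

    def rec(i: int, j: int, can_stack: bool) -> int:
        if j - i < min_loop + 1:
            return 0
        b = rec(i + 1, j, False)
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in PAIRS:
                w = WEIGHT[(seq[i], seq[k])] + (1 if (can_stack and k == j) else 0)
                b = max(b, w + rec(i + 1, k - 1, True) + rec(k + 1, j, False))
        return b

    return rec(0, len(seq) - 1, False)


def parsimony_probability_series(j: int, m: int, kmax: int = 200) -> float:
    """Parsimony probability by summing the Poisson substitution-count
    series with the exact k-event Jukes-Cantor difference probability."""
    if j <= 0:
        return 1.0
    if m <= 0 or j > m:
        return 0.0
    d = j / m
    if d >= 0.75:
        return 0.0
    mu = -0.75 * np.log1p(-4.0 * d / 3.0)
    k = np.arange(kmax)
    pk = poisson.pmf(k, mu)
    p_diff_given_k = 0.75 * (1.0 - (-1.0 / 3.0) ** k)
    visible = float(np.sum(pk * p_diff_given_k))
    identical = float(np.sum(pk * (1.0 - p_diff_given_k)))
    r1 = min(1.0, float(pk[1]) / visible)  # one event is always visible
    s0 = min(1.0, float(pk[0]) / identical)
    return (r1 ** j) * (s0 ** (m - j))


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))
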