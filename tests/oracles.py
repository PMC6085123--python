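"""Independent brute-force oracles used to freeze expected test values.

These deliberately avoid the code paths they check: the Fisher oracle
enumerates the full hypergeometric distribution, and the BH oracle applies
the step-up definition literally.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration over fixed margins.

    Sums hypergeometric probabilities of every table whose probability is
    at most that of the observed table (relative tie tolerance 1e-7).
    """
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    xs = np.arange(lo, hi + 1)
    probs = hypergeom.pmf(xs, n, row1, col1)
    p_obs = probs[xs == a][0]
    return float(probs[probs <= p_obs * (1 + 1e-7)].sum())


def bh_stepup_oracle(pvals: list[float]) -> list[float]:
    """Literal Benjamini–Hochberg step-up: q_i = min_{p_(j) >= p_i} m p_(j)/j."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q_sorted = [min(1.0, pvals[order[j]] * m / (j + 1)) for j in range(m)]
    for j in range(m - 2, -1, -1):
        q_sorted[j] = min(q_sorted[j], q_sorted[j + 1])
    q = [0.0] * m
    for j, i in enumerate(order):
        q[i] = q_sorted[j]
    return q
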