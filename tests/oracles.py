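"""Independent brute-force oracles for the exact Fisher statistics.

Kept free of any senquad internals: exact rational tail sums via integer
binomials, and a dense log-grid likelihood search for the conditional-MLE
odds ratio.
"""

from fractions import Fraction
from math import comb

import numpy as np


def support(a, b, c, d):
    n, row1, col1 = a + b + c + d, a + b, a + c
    return max(0, row1 + col1 - n), min(row1, col1)


def exact_p_greater(a, b, c, d):
    """P(X >= a) for central hypergeometric, exact rational arithmetic."""
    n, row1, col1 = a + b + c + d, a + b, a + c
    _, x_max = support(a, b, c, d)
    num = sum(comb(row1, x) * comb(n - row1, col1 - x) for x in range(a, x_max + 1))
    return Fraction(num, comb(n, col1))


def exact_p_less(a, b, c, d):
    n, row1, col1 = a + b + c + d, a + b, a + c
    x_min, _ = support(a, b, c, d)
    num = sum(comb(row1, x) * comb(n - row1, col1 - x) for x in range(x_min, a + 1))
    return Fraction(num, comb(n, col1))


def grid_cmle_or(a, b, c, d, log_psi_range=(-15.0, 15.0)):
    """Dense log-psi grid maximization of the noncentral hypergeometric
    likelihood of the observed cell (coarse pass then local refinement to
    ~1e-5 relative); returns 0/inf at the support boundary."""
    x_min, x_max = support(a, b, c, d)
    if a == x_min:
        return 0.0
    if a == x_max:
        return float("inf")
    n, row1, col1 = a + b + c + d, a + b, a + c
    xs = np.arange(x_min, x_max + 1)
    log_w = np.array(
        [np.log(comb(row1, int(x))) + np.log(comb(n - row1, col1 - int(x)))
         for x in xs]
    )

    def argmax_on(t):
        logits = log_w[:, None] + np.outer(xs, t)
        log_lik = logits[xs == a][0] - np.logaddexp.reduce(logits, axis=0)
        return t[np.argmax(log_lik)]

    coarse = np.linspace(*log_psi_range, 3001)
    step = coarse[1] - coarse[0]
    t0 = argmax_on(coarse)
    fine = np.linspace(t0 - 2 * step, t0 + 2 * step, 4001)
    return float(np.exp(argmax_on(fine)))
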