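"""Independent brute-force oracles used by the test suite.

Each function recomputes a quantity by the most direct route available
(enumeration, naive double loops, grid search) without sharing code with the
package implementation it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom


def naive_breslow_loglik(beta, x, time, event):
    """O(n^2) Breslow partial log-likelihood for a single covariate."""
    ll = 0.0
    for i in range(len(time)):
        if event[i]:
            risk = [j for j in range(len(time)) if time[j] >= time[i]]
            ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


def grid_cox_beta(x, time, event, lo=-10.0, hi=10.0):
    """Partial-likelihood maximizer by three-stage grid refinement (~1e-7)."""
    for _ in range(3):
        grid = np.linspace(lo, hi, 2001)
        ll = np.array([naive_breslow_loglik(b, x, time, event) for b in grid])
        best = grid[np.argmax(ll)]
        span = (hi - lo) / 2000
        lo, hi = best - 2 * span, best + 2 * span
    return best


def brute_logrank_chi2(time, event, in_group1):
    """Sum of (O - E) and hypergeometric variances over the event times."""
    o_minus_e = 0.0
    v = 0.0
    for t in sorted(set(time[event == 1])):
        n_t = int((time >= t).sum())
        n1_t = int(((time >= t) & in_group1).sum())
        d_t = int(((time == t) & (event == 1)).sum())
        d1_t = int(((time == t) & (event == 1) & in_group1).sum())
        o_minus_e += d1_t - d_t * (n1_t / n_t)
        if n_t > 1:
            v += (
                d_t
                * (n1_t / n_t)
                * (1 - n1_t / n_t)
                * (n_t - d_t)
                / (n_t - 1)
            )
    return o_minus_e**2 / v


def fisher_enumeration_p(table):
    """Two-sided Fisher p by full enumeration of tables with fixed margins."""
    a, b = table[0]
    c, d = table[1]
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    rv = hypergeom(n, row1, col1)
    support = np.arange(max(0, col1 - (c + d)), min(row1, col1) + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(probs[probs <= p_obs * (1 + 1e-7)].sum())


def mann_whitney_auc(scores, is_case):
    """Probability a random case outscores a random control (ties count 1/2)."""
    cases = scores[is_case]
    controls = scores[~is_case]
    wins = 0.0
    for s in cases:
        wins += (s > controls).sum() + 0.5 * (s == controls).sum()
    return wins / (len(cases) * len(controls))


def pearson_formula(x, y):
    """Textbook product-moment r and its two-sided t-test p."""
    from scipy.stats import t as tdist

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    r = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
    tstat = r * np.sqrt((n - 2) / (1 - r**2))
    return r, 2 * tdist.sf(abs(tstat), df=n - 2)
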