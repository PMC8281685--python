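"""Cox proportional-hazards internals: Breslow partial likelihood and Newton-Raphson.

All public fitting functions in :mod:`irgpsig.survival` and
:mod:`irgpsig.signature` route through this module.  Ties are handled with the
Breslow approximation throughout: every event at a tied time uses the full
risk set of that time in the denominator.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "CoxSeparationError",
    "CoxConvergenceError",
    "breslow_loglik",
    "breslow_score_info",
    "newton_cox",
]


class CoxSeparationError(RuntimeError):
    """Monotone likelihood: a covariate perfectly orders events (no finite MLE)."""


class CoxConvergenceError(RuntimeError):
    """Newton-Raphson failed to reach the gradient tolerance."""


def _order_by_time(time, event, X):
    order = np.argsort(time, kind="stable")
    return time[order], event[order], X[order]


def breslow_loglik(beta, X, time, event):
    """Breslow partial log-likelihood at ``beta``.

    Risk set at an event time t is {j : t_j >= t}; subjects censored at t are
    still at risk at t.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    t, d, x = _order_by_time(time, event, X)
    eta = x @ beta
    # cumulative risk-set sums from the largest time downwards
    rev = np.exp(eta[::-1]).cumsum()[::-1]
    ll = 0.0
    n = len(t)
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        n_ev = int(d[i:j].sum())
        if n_ev:
            ll += eta[i:j][d[i:j] == 1].sum() - n_ev * np.log(rev[i])
        i = j
    return ll


def breslow_score_info(beta, X, time, event):
    """Gradient and observed information of the Breslow partial log-likelihood."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    t, d, x = _order_by_time(time, event, X)
    n, p = x.shape
    w = np.exp(x @ beta)
    # reverse-cumulative risk-set aggregates
    s0 = w[::-1].cumsum()[::-1]                                  # (n,)
    s1 = (w[:, None] * x)[::-1].cumsum(axis=0)[::-1]             # (n, p)
    xxw = w[:, None, None] * (x[:, :, None] * x[:, None, :])
    s2 = xxw[::-1].cumsum(axis=0)[::-1]                          # (n, p, p)
    grad = np.zeros(p)
    info = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        n_ev = int(d[i:j].sum())
        if n_ev:
            xbar = s1[i] / s0[i]
            grad += x[i:j][d[i:j] == 1].sum(axis=0) - n_ev * xbar
            info += n_ev * (s2[i] / s0[i] - np.outer(xbar, xbar))
        i = j
    return grad, info


def newton_cox(X, time, event, *, tol=1e-8, max_iter=100, beta0=None):
    """Maximize the Breslow partial likelihood by damped Newton-Raphson.

    Returns ``(beta, se, loglik)``.  Convergence criterion is
    ``max|gradient| < tol``.  Raises :class:`CoxSeparationError` when the
    estimate diverges (monotone likelihood) and :class:`CoxConvergenceError`
    after ``max_iter`` iterations.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if np.any(X.std(axis=0) == 0):
        idx = int(np.flatnonzero(X.std(axis=0) == 0)[0])
        raise ValueError(f"covariate {idx} is constant; coefficient inestimable")
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    ll = breslow_loglik(beta, X, time, event)
    for _ in range(max_iter):
        grad, info = breslow_score_info(beta, X, time, event)
        if np.max(np.abs(grad)) < tol:
            cov = np.linalg.inv(info)
            return beta, np.sqrt(np.diag(cov)), ll
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise CoxSeparationError(
                "singular information matrix; monotone likelihood suspected"
            ) from exc
        # step-halving line search
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new = breslow_loglik(cand, X, time, event)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta, ll = cand, ll_new
        if np.max(np.abs(beta)) > 50:
            idx = int(np.argmax(np.abs(beta)))
            raise CoxSeparationError(
                f"coefficient {idx} diverged (|beta|>50): separation in covariate {idx}"
            )
    raise CoxConvergenceError(f"no convergence in {max_iter} Newton iterations")
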