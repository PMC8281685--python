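"""Censored-survival evaluation.

Kaplan-Meier curves, the two-group log-rank test, multivariable Cox
proportional-hazards fits (Breslow ties, Wald inference), the
cumulative-case / dynamic-control time-dependent ROC estimated by
Kaplan-Meier conditioning, and ROC-based cutoff selection via Youden's J.

Survival data is carried as a :class:`pandas.DataFrame` with columns
``time`` (follow-up, any single consistent unit, > 0) and ``event``
(1 = event observed, 0 = right-censored), indexed by sample ID; additional
columns are treated as covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._cox import breslow_score_info, newton_cox

__all__ = [
    "KMCurve",
    "TimeDependentROC",
    "km_estimate",
    "logrank_test",
    "fit_cox",
    "time_dependent_roc",
    "select_cutoff",
]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate.

    ``times`` are the distinct event times in ascending order; ``survival``
    holds S(t) just after each, so the curve is the right-continuous step
    function S(t) = survival[i] for times[i] <= t < times[i+1] and 1 before
    the first event.
    """

    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def evaluate(self, t: float) -> float:
        """S(t) of the right-continuous step function."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class TimeDependentROC:
    """Time-dependent ROC at horizon ``horizon``.

    Cases are subjects with an event by the horizon, controls subjects
    event-free past it; sensitivity and specificity are estimated under
    censoring by conditioning Kaplan-Meier estimates on marker strata.
    ``thresholds`` are descending and include -inf/+inf endpoints so the
    curve spans (0,0) to (1,1) in (1-specificity, sensitivity) space.
    """

    horizon: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float = field(default=np.nan)


def _as_time_event(surv: pd.DataFrame):
    time = np.asarray(surv["time"], dtype=float)
    event = np.asarray(surv["event"], dtype=int)
    return time, event


def km_estimate(surv: pd.DataFrame) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Censored observations reduce the risk set without introducing steps;
    all-censored input yields S identically 1 (no event times).
    """
    time, event = _as_time_event(surv)
    if len(time) == 0:
        raise ValueError("empty survival data")
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    event_times = np.unique(time[event == 1])
    n = len(time)
    surv_est, at_risk, n_ev = [], [], []
    s = 1.0
    for t in event_times:
        r = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d / r
        surv_est.append(s)
        at_risk.append(r)
        n_ev.append(d)
    return KMCurve(
        times=event_times,
        survival=np.asarray(surv_est, dtype=float),
        n_at_risk=np.asarray(at_risk, dtype=int),
        n_events=np.asarray(n_ev, dtype=int),
    )


def logrank_test(surv: pd.DataFrame, groups) -> tuple[float, float]:
    """Two-group log-rank test.

    Returns ``(chi_square, p_value)`` from the observed-minus-expected
    statistic with the hypergeometric variance, 1 degree of freedom.
    """
    time, event = _as_time_event(surv)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(levels)}")
    g1 = groups == levels[0]
    if g1.sum() == 0 or (~g1).sum() == 0:
        raise ValueError("a group has zero samples")
    if event.sum() == 0:
        raise ValueError("no events observed")
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n_t = int(at_risk.sum())
        n1_t = int((at_risk & g1).sum())
        d_t = int(((time == t) & (event == 1)).sum())
        d1_t = int(((time == t) & (event == 1) & g1).sum())
        o_minus_e += d1_t - d_t * n1_t / n_t
        if n_t > 1:
            var += d_t * (n1_t / n_t) * (1 - n1_t / n_t) * (n_t - d_t) / (n_t - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def fit_cox(surv: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Multivariable Cox proportional-hazards fit.

    Newton-Raphson maximization of the Breslow partial likelihood to a
    gradient norm below 1e-8.  Returns one row per covariate with columns
    ``coef``, ``se``, ``hr``, ``hr_lower``, ``hr_upper`` (normal-approximation
    95% CI on the log scale) and two-sided Wald ``p``.

    Raises on constant covariates, separation, or non-convergence, naming
    the offending covariate.
    """
    missing = [c for c in covariates if c not in surv.columns]
    if missing:
        raise ValueError(f"covariates not in survival table: {missing}")
    X = surv[covariates].to_numpy(dtype=float)
    time, event = _as_time_event(surv)
    const = [covariates[i] for i in np.flatnonzero(X.std(axis=0) == 0)]
    if const:
        raise ValueError(f"constant covariate(s): {const}")
    try:
        beta, se, _ = newton_cox(X, time, event)
    except RuntimeError as exc:
        msg = str(exc)
        for i, name in enumerate(covariates):
            msg = msg.replace(f"covariate {i}", f"covariate '{name}'")
        raise type(exc)(msg) from exc
    z = beta / se
    return pd.DataFrame(
        {
            "coef": beta,
            "se": se,
            "hr": np.exp(beta),
            "hr_lower": np.exp(beta - 1.959963984540054 * se),
            "hr_upper": np.exp(beta + 1.959963984540054 * se),
            "p": 2 * stats.norm.sf(np.abs(z)),
        },
        index=pd.Index(covariates, name="covariate"),
    )


def cox_score_test(surv: pd.DataFrame, covariate) -> tuple[float, float]:
    """Score (Rao) test of a single covariate at beta = 0.

    On tie-free data with a binary covariate this coincides exactly with the
    log-rank test.
    """
    X = np.asarray(covariate, dtype=float)[:, None]
    time, event = _as_time_event(surv)
    grad, info = breslow_score_info(np.zeros(1), X, time, event)
    chi2 = float(grad[0] ** 2 / info[0, 0])
    return chi2, float(stats.chi2.sf(chi2, df=1))


def time_dependent_roc(scores, surv: pd.DataFrame, horizon: float) -> TimeDependentROC:
    """Cumulative-case / dynamic-control ROC at ``horizon``.

    With S-hat the Kaplan-Meier estimate and X the marker::

        sensitivity(c) = (1 - S(t*| X > c)) * P(X > c) / (1 - S(t*))
        specificity(c) =      S(t*| X <= c) * P(X <= c) /     S(t*)

    evaluated over every observed marker value (plus -inf/+inf endpoints);
    conditional survival within marker strata comes from stratum-wise
    Kaplan-Meier curves (right-continuous steps).  AUC by the trapezoid rule.
    Estimates are clipped to [0, 1] (finite-sample KM conditioning can
    overshoot slightly).
    """
    scores = np.asarray(scores, dtype=float)
    time, event = _as_time_event(surv)
    if len(scores) != len(time):
        raise ValueError("scores and survival data have different lengths")
    if ((time <= horizon) & (event == 1)).sum() == 0:
        raise ValueError(f"no events observed before horizon {horizon}")
    km_all = km_estimate(surv)
    s_all = km_all.evaluate(horizon)
    if s_all >= 1.0 or s_all <= 0.0:
        raise ValueError("degenerate overall survival at horizon")
    n = len(scores)
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1], [-np.inf]))
    sens, spec = [], []
    for c in thresholds:
        above = scores > c
        p_above = above.sum() / n
        if p_above == 0.0:
            se = 0.0
        else:
            s_hi = km_estimate(surv[above]).evaluate(horizon)
            se = (1.0 - s_hi) * p_above / (1.0 - s_all)
        if p_above == 1.0:
            sp = 0.0
        else:
            s_lo = km_estimate(surv[~above]).evaluate(horizon)
            sp = s_lo * (1.0 - p_above) / s_all
        sens.append(min(max(se, 0.0), 1.0))
        spec.append(min(max(sp, 0.0), 1.0))
    sens = np.asarray(sens)
    spec = np.asarray(spec)
    # integrate along descending thresholds (the curve's natural traversal
    # from (0,0) to (1,1)); sorting by FPR instead would let float noise in
    # tied FPR values scramble vertically stacked points
    auc = float(np.trapezoid(sens, 1.0 - spec))
    return TimeDependentROC(
        horizon=float(horizon),
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
    )


def select_cutoff(roc: TimeDependentROC) -> float:
    """Marker cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Only finite thresholds are eligible.  Ties are broken toward the
    smallest threshold; a completely flat curve returns the smallest
    threshold with a warning.
    """
    finite = np.isfinite(roc.thresholds)
    if not finite.any():
        raise ValueError("ROC has no finite thresholds")
    thr = roc.thresholds[finite]
    j = roc.sensitivity[finite] + roc.specificity[finite] - 1.0
    if np.allclose(j, j[0]):
        warnings.warn("flat ROC curve: Youden's J is constant; returning smallest threshold")
        return float(thr.min())
    best = j.max()
    return float(thr[np.isclose(j, best)].min())
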