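"""Survival machinery: Kaplan–Meier, log-rank, Cox PH, cutpoint search.

The product-limit estimator and the G-group log-rank test are implemented
directly (they expose per-time at-risk/event tables and Greenwood variances
that downstream reporting needs); Cox proportional-hazards fits delegate to
lifelines with Efron tie handling. ``select_cutpoint`` is a maximally
selected rank statistic search: it scans admissible marker thresholds and
returns the one maximizing the absolute standardized two-group log-rank
statistic, subject to a minimum group-proportion constraint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalCurve",
    "CoxFit",
    "CutpointResult",
    "km_estimate",
    "survival_at",
    "logrank_test",
    "cox_fit",
    "select_cutpoint",
]


@dataclass
class SurvivalCurve:
    """Kaplan–Meier step function with Greenwood variance and log-log CI."""

    times: np.ndarray          # distinct event times, increasing
    survival: np.ndarray       # S(t) just after each event time
    variance: np.ndarray       # Greenwood variance of S(t)
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "n_risk": self.n_risk,
                "n_event": self.n_event,
            }
        )


@dataclass
class CoxFit:
    """Per-covariate hazard ratios with Wald CIs and p-values."""

    summary: pd.DataFrame      # index: covariate; coef, hr, ci_lower, ci_upper, p
    scope: str                 # "univariate" | "multivariate"
    converged: bool


@dataclass
class CutpointResult:
    cutoff: float
    statistic: float           # standardized log-rank statistic at the cutoff
    minprop: float
    n_high: int
    n_low: int


def _check_times(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("need at least one record")
    if (time < 0).any():
        raise ValueError("negative survival times")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event flags must be 0 or 1")
    return time, event


def km_estimate(time, event, alpha: float = 0.05) -> SurvivalCurve:
    """Product-limit estimate with Greenwood variance and log-log CIs."""
    time, event = _check_times(time, event)
    order = np.argsort(time, kind="mergesort")
    time, event = time[order], event[order]
    event_times = np.unique(time[event == 1])
    n = time.size
    S = 1.0
    cum = 0.0  # running sum d_i / (n_i (n_i - d_i))
    surv, var, n_risk, n_event = [], [], [], []
    for t in event_times:
        at_risk = int(np.sum(time >= t))
        d = int(np.sum((time == t) & (event == 1)))
        S *= 1.0 - d / at_risk
        if at_risk > d:
            cum += d / (at_risk * (at_risk - d))
        else:
            cum = np.inf
        surv.append(S)
        var.append(S**2 * cum if np.isfinite(cum) else 0.0)
        n_risk.append(at_risk)
        n_event.append(d)
    surv = np.asarray(surv)
    var = np.asarray(var)
    lo, hi = _loglog_ci(surv, var, alpha)
    return SurvivalCurve(
        times=event_times,
        survival=surv,
        variance=var,
        ci_lower=lo,
        ci_upper=hi,
        n_risk=np.asarray(n_risk),
        n_event=np.asarray(n_event),
    )


def _loglog_ci(surv, var, alpha):
    z = stats.norm.ppf(1 - alpha / 2)
    lo = np.zeros_like(surv)
    hi = np.ones_like(surv)
    interior = (surv > 0) & (surv < 1)
    s = surv[interior]
    se_log = np.sqrt(var[interior]) / np.maximum(s * np.abs(np.log(s)), np.finfo(float).tiny)
    theta = np.exp(z * se_log)
    lo[interior] = s ** theta
    hi[interior] = s ** (1 / theta)
    hi[surv == 0] = 0.0
    lo[surv == 1] = 1.0
    return lo, hi


def survival_at(curve: SurvivalCurve, t: float):
    """Right-continuous step-function evaluation with CI.

    Returns ``(S(t), (lo, hi), beyond_followup)``. Querying beyond the last
    event time returns the last value with the flag set.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    if curve.times.size == 0 or t < curve.times[0]:
        return 1.0, (1.0, 1.0), False
    idx = np.searchsorted(curve.times, t, side="right") - 1
    beyond = t > curve.times[-1]
    return (
        float(curve.survival[idx]),
        (float(curve.ci_lower[idx]), float(curve.ci_upper[idx])),
        bool(beyond),
    )


def logrank_test(time, event, groups):
    """G-group log-rank test.

    Builds the observed-minus-expected vector over event times with the
    multivariate hypergeometric variance and evaluates
    (O−E)ᵀ V⁻¹ (O−E) on G−1 components against chi-square(G−1). A singular
    variance matrix falls back to the Moore–Penrose inverse with a warning.
    Returns ``(chi2, df, p)``.
    """
    time, event = _check_times(time, event)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    G = levels.size
    if G < 2:
        raise ValueError("need at least two groups")
    for lev in levels:
        if not (groups == lev).any():
            raise ValueError(f"empty group {lev!r}")
    gidx = np.searchsorted(levels, groups)
    event_times = np.unique(time[event == 1])
    O = np.zeros(G)
    E = np.zeros(G)
    V = np.zeros((G, G))
    for t in event_times:
        at_risk = time >= t
        n_t = at_risk.sum()
        d_t = int(np.sum((time == t) & (event == 1)))
        n_g = np.bincount(gidx[at_risk], minlength=G).astype(float)
        d_g = np.bincount(gidx[(time == t) & (event == 1)], minlength=G).astype(float)
        O += d_g
        E += d_t * n_g / n_t
        if n_t > 1:
            frac = n_g / n_t
            mult = d_t * (n_t - d_t) / (n_t - 1)
            V += mult * (np.diag(frac) - np.outer(frac, frac))
    u = (O - E)[:-1]
    Vr = V[:-1, :-1]
    try:
        sol = np.linalg.solve(Vr, u)
    except np.linalg.LinAlgError:
        warnings.warn("singular log-rank variance matrix; using pseudo-inverse", RuntimeWarning)
        sol = np.linalg.pinv(Vr) @ u
    chi2 = float(u @ sol)
    chi2 = max(chi2, 0.0)
    df = G - 1
    p = float(stats.chi2.sf(chi2, df))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return chi2, df, p


def _standardized_logrank(time, event, high_mask):
    """Two-group standardized log-rank statistic (O−E)/√V for the high group."""
    event_times = np.unique(time[event == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = time >= t
        n_t = at_risk.sum()
        d_t = int(np.sum((time == t) & (event == 1)))
        n1 = int(np.sum(at_risk & high_mask))
        d1 = int(np.sum((time == t) & (event == 1) & high_mask))
        o_minus_e += d1 - d_t * n1 / n_t
        if n_t > 1:
            var += d_t * (n1 / n_t) * (1 - n1 / n_t) * (n_t - d_t) / (n_t - 1)
    if var <= 0:
        return 0.0
    return o_minus_e / np.sqrt(var)


def cox_fit(covariates: pd.DataFrame, time, event, scope: str = "univariate") -> CoxFit:
    """Cox proportional-hazards fit (lifelines, Efron tie handling).

    ``covariates`` is a samples × covariates DataFrame. Returns per-covariate
    coefficients, hazard ratios, 95% Wald CIs and p-values. Non-convergence or
    perfect separation is reported via ``converged=False`` rather than raised.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    covariates = pd.DataFrame(covariates)
    time, event = _check_times(time, event)
    if covariates.shape[0] != time.size:
        raise ValueError("covariate rows must match the number of records")
    nunique = covariates.nunique()
    if (nunique <= 1).any():
        bad = list(nunique.index[nunique <= 1])
        raise ValueError(f"constant covariate(s): {bad}")
    if event.sum() < covariates.shape[1] + 1:
        raise ValueError("too few events for the number of covariates")
    df = covariates.copy()
    df["_time"] = time
    df["_event"] = event
    cph = CoxPHFitter()
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="_time", event_col="_event")
    except ConvergenceError:
        converged = False
    if not converged:
        summary = pd.DataFrame(
            np.nan,
            index=covariates.columns,
            columns=["coef", "hr", "ci_lower", "ci_upper", "p"],
        )
        return CoxFit(summary=summary, scope=scope, converged=False)
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "ci_lower": s["exp(coef) lower 95%"],
            "ci_upper": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    summary.index.name = "covariate"
    return CoxFit(summary=summary, scope=scope, converged=True)


def select_cutpoint(marker, time, event, minprop: float = 0.1) -> CutpointResult:
    """Maximally selected log-rank cutpoint for a continuous marker.

    Candidate thresholds are midpoints between consecutive distinct marker
    values whose high/low split leaves at least ``minprop`` of the samples on
    each side. The returned cutoff maximizes the absolute standardized
    two-group log-rank statistic (ties break toward the smaller threshold).
    """
    marker = np.asarray(marker, dtype=float)
    time, event = _check_times(time, event)
    if marker.size != time.size:
        raise ValueError("marker and survival records must have equal length")
    if not (0 < minprop <= 0.5):
        raise ValueError("minprop must be in (0, 0.5]")
    distinct = np.unique(marker)
    if distinct.size < 2:
        raise ValueError("marker needs at least two distinct values")
    n = marker.size
    lo_count = int(np.ceil(minprop * n))
    best = None
    for i in range(distinct.size - 1):
        cut = 0.5 * (distinct[i] + distinct[i + 1])
        high = marker > cut
        n_high = int(high.sum())
        if n_high < lo_count or n - n_high < lo_count:
            continue
        z = abs(_standardized_logrank(time, event, high))
        if best is None or z > best[1] + 1e-12:
            best = (cut, z, n_high)
    if best is None:
        raise ValueError("no admissible split satisfies the minprop constraint")
    cut, z, n_high = best
    return CutpointResult(cutoff=float(cut), statistic=float(z), minprop=minprop,
                          n_high=n_high, n_low=n - n_high)
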