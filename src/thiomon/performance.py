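"""Discrimination and calibration metrics for the survival risk model.

Royston's D statistic rank-transforms the linear predictor to standard
normal order statistics (Blom scores) scaled by kappa = sqrt(8/pi) and
refits a univariate Cox model; its coefficient is interpretable as the log
hazard ratio between prognostic halves, and R2_D = (D^2/kappa^2) /
(pi^2/6 + D^2/kappa^2). The calibration slope is the coefficient of the
fixed, externally computed linear predictor in a univariate Cox refit.
Grouped calibration compares mean predicted risk with the Kaplan-Meier
observed risk in tenths of predicted risk; jackknife pseudo-observations
of F(t) = 1 - S(t) feed a running-line smoother for the smooth curve (they
may legitimately fall outside [0, 1]).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from statsmodels.nonparametric.smoothers_lowess import lowess
from scipy import stats

from ._cox import cox_fit
from .cohort import to_design_matrix
from .imputation import ImputedStack, rubin_pool
from .risk_model import PARAMETERS, PublishedModel, risk_from_lp

__all__ = [
    "KAPPA",
    "PerformanceReport",
    "CalibrationCurve",
    "royston_d",
    "r2_from_d",
    "calibration_slope",
    "pseudo_values",
    "grouped_calibration",
    "evaluate",
]

KAPPA = math.sqrt(8.0 / math.pi)


@dataclass
class MetricEstimate:
    value: float
    se: float

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.value - 1.96 * self.se, self.value + 1.96 * self.se)


@dataclass
class PerformanceReport:
    calibration_slope: MetricEstimate
    royston_d: MetricEstimate
    r2_d: float
    r2_ci: tuple[float, float]
    horizon: float
    n: int
    events: int

    @property
    def implied_hr(self) -> float:
        return math.exp(self.royston_d.value)


@dataclass
class CalibrationCurve:
    groups: pd.DataFrame         # group, n, mean_predicted, observed, ci bounds
    smooth: pd.DataFrame         # predicted grid -> smoothed pseudo-value mean
    horizon: float


def royston_d(linear_predictors, times, events) -> MetricEstimate:
    """Royston-Sauerbrei D statistic with model-based standard error."""
    lp = np.asarray(linear_predictors, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if np.ptp(lp) == 0:
        warnings.warn("all linear predictors tied; D = 0")
        return MetricEstimate(0.0, np.nan)
    n = lp.size
    ranks = stats.rankdata(lp, method="average")
    blom = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    res = cox_fit(blom / KAPPA, t, e)
    return MetricEstimate(float(res.beta[0]), float(res.se[0]))


def r2_from_d(D: float) -> float:
    """Explained variation on the log-hazard scale implied by D."""
    if not math.isfinite(D):
        raise ValueError("D must be finite")
    a = D * D / (KAPPA * KAPPA)
    return a / (math.pi ** 2 / 6.0 + a)


def calibration_slope(linear_predictors, times, events) -> MetricEstimate:
    """Coefficient of the fixed linear predictor in a univariate Cox refit."""
    lp = np.asarray(linear_predictors, dtype=float)
    if np.ptp(lp) == 0:
        raise ValueError("degenerate (constant) linear predictor")
    res = cox_fit(lp, np.asarray(times, float), np.asarray(events, int))
    return MetricEstimate(float(res.beta[0]), float(res.se[0]))


def _km_survival_at(times, events, horizon) -> float:
    """Kaplan-Meier S(horizon)."""
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order]
    ev_times = np.unique(ts[es == 1])
    ev_times = ev_times[ev_times <= horizon]
    if ev_times.size == 0:
        return 1.0
    d = np.array([((ts == u) & (es == 1)).sum() for u in ev_times])
    n_at = ts.size - np.searchsorted(ts, ev_times, side="left")
    return float(np.prod(1.0 - d / n_at))


def pseudo_values(times, events, horizon: float) -> np.ndarray:
    """Jackknife pseudo-observations of F(horizon) = 1 - S(horizon).

    pseudo_i = n * Fhat - (n - 1) * Fhat_(-i), with the leave-one-out
    Kaplan-Meier computed exactly for every subject. With no censoring
    before the horizon they reduce to the event indicators at the horizon.
    """
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    n = t.size
    if n < 3:
        raise ValueError("need at least 3 subjects for pseudo-values")
    if horizon > t.max():
        warnings.warn("horizon after the last observed time")

    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order]
    ev_times = np.unique(ts[es == 1])
    ev_times = ev_times[ev_times <= horizon]
    K = ev_times.size
    if K == 0:
        return np.zeros(n)
    d = np.array([((ts == u) & (es == 1)).sum() for u in ev_times], dtype=float)
    n_at = (ts.size - np.searchsorted(ts, ev_times, side="left")).astype(float)

    # prefix products of the full-sample factors (B) and the factors with one
    # extra subject removed from every risk set (A)
    fac_B = 1.0 - d / n_at
    fac_A = np.where(n_at > 1, 1.0 - d / np.maximum(n_at - 1.0, 1.0), 1.0)
    B = np.concatenate(([1.0], np.cumprod(fac_B)))   # B[k] = prod of first k
    A = np.concatenate(([1.0], np.cumprod(fac_A)))
    S_full = B[K]

    # m_i = number of event times <= min(t_i, horizon)
    m = np.searchsorted(ev_times, np.minimum(ts, horizon), side="right")
    with np.errstate(divide="ignore", invalid="ignore"):
        S_loo = A[m] * (B[K] / B[m])                 # censored-subject formula
    is_event_in = (es == 1) & (ts <= horizon)
    if np.any(is_event_in):
        k = np.searchsorted(ev_times, ts[is_event_in])     # position of own time
        nk = n_at[k]
        dk = d[k]
        own = np.where(nk > 1, 1.0 - (dk - 1.0) / np.maximum(nk - 1.0, 1.0), 1.0)
        S_loo[is_event_in] = A[k] * own * (B[K] / B[k + 1])
    F_full = 1.0 - S_full
    pseudo_sorted = n * F_full - (n - 1) * (1.0 - S_loo)
    out = np.empty(n)
    out[order] = pseudo_sorted
    return out


def _observed_risk_km(times, events, horizon) -> tuple[float, float, float]:
    """1 - KM(horizon) with a Greenwood (log-log) confidence interval."""
    km = KaplanMeierFitter().fit(times, events)
    s = float(km.predict(horizon))
    ci = km.confidence_interval_
    idx = ci.index[ci.index <= horizon]
    if len(idx):
        lo_s, hi_s = ci.loc[idx[-1]].to_numpy()
    else:
        lo_s = hi_s = s
    return 1.0 - s, 1.0 - hi_s, 1.0 - lo_s


def grouped_calibration(
    predicted_risks,
    times,
    events,
    g: int = 10,
    horizon: float = 5.0,
    span: float = 0.75,
) -> CalibrationCurve:
    """Grouped and smoothed calibration at a horizon.

    Subjects are split into g equal-sized groups of predicted risk (ties
    broken by stable subject order); observed group risk is the
    Kaplan-Meier complement with Greenwood interval. The smooth curve is a
    lowess running-line of the pseudo-values on predicted risk, evaluated
    on an even grid.
    """
    pred = np.asarray(predicted_risks, float)
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    if np.ptp(pred) == 0:
        g = 1  # degenerate: a single group, one point on the identity line
    order = np.argsort(pred, kind="stable")
    rows = []
    for gi, idx in enumerate(np.array_split(order, g), start=1):
        obs, lo, hi = _observed_risk_km(t[idx], e[idx], horizon)
        rows.append({"group": gi, "n": idx.size,
                     "mean_predicted": float(pred[idx].mean()),
                     "observed": obs, "observed_lo": lo, "observed_hi": hi})
    groups = pd.DataFrame(rows)

    ps = pseudo_values(t, e, horizon)
    sm = lowess(ps, pred, frac=span, return_sorted=True)
    grid = np.linspace(pred.min(), pred.max(), 50)
    smooth = pd.DataFrame({
        "predicted": grid,
        "observed_smooth": np.interp(grid, sm[:, 0], sm[:, 1]),
    })
    return CalibrationCurve(groups, smooth, horizon)


def _linear_predictor_for(model, design: pd.DataFrame) -> np.ndarray:
    """Scoring-scale linear predictor (shrinkage included) for any model
    exposing coefficients and a shrinkage factor."""
    coef = model.coefficients
    params = [p for p in PARAMETERS if p in coef] or list(coef)
    X = design[params].to_numpy(dtype=float)
    beta = np.array([coef[p] for p in params])
    return model.shrinkage * (X @ beta)


def evaluate(
    model,
    data,
    horizon: float = 5.0,
    subgroup: str | None = None,
    g: int = 10,
):
    """Evaluate a fixed model (no refitting) on a cohort or imputed stack.

    ``model`` is a PublishedModel or a CoxModelFit with a baseline at the
    horizon. Metrics are computed per completed dataset and pooled by
    Rubin's rules; calibration curves are returned per imputation. With
    ``subgroup`` set to a cohort column, a report per level is returned
    instead.
    """
    if isinstance(data, ImputedStack):
        datasets = data.datasets
    else:
        datasets = [data]

    if subgroup is not None:
        levels = sorted(datasets[0][subgroup].dropna().unique())
        out = {}
        for lev in levels:
            sub = ImputedStack([d[d[subgroup] == lev].reset_index(drop=True)
                                for d in datasets], 0, 0)
            out[lev] = evaluate(model, sub, horizon=horizon, g=g)
        return out

    if isinstance(model, PublishedModel):
        scoring = model
    else:
        scoring = model.as_scoring_rule(horizon)

    slopes, ds, curves = [], [], []
    for d in datasets:
        design = d if set(PARAMETERS) <= set(d.columns) else to_design_matrix(d)
        lp = _linear_predictor_for(scoring, design)
        t = design["followup_time"].to_numpy(dtype=float)
        e = design["event"].to_numpy(dtype=int)
        slopes.append(calibration_slope(lp, t, e))
        ds.append(royston_d(lp, t, e))
        risks = np.asarray(risk_from_lp(lp / max(scoring.shrinkage, 1e-12), scoring))
        curves.append(grouped_calibration(risks, t, e, g=g, horizon=horizon))

    if len(datasets) > 1:
        slope_p = rubin_pool([s.value for s in slopes], [s.se ** 2 for s in slopes])
        d_p = rubin_pool([x.value for x in ds], [x.se ** 2 for x in ds])
        slope = MetricEstimate(slope_p.estimate, slope_p.se)
        D = MetricEstimate(d_p.estimate, d_p.se)
    else:
        slope, D = slopes[0], ds[0]

    r2 = r2_from_d(D.value)
    r2_ci = tuple(sorted(r2_from_d(b) for b in D.ci95))
    report = PerformanceReport(
        calibration_slope=slope, royston_d=D, r2_d=r2, r2_ci=r2_ci,
        horizon=horizon, n=len(datasets[0]),
        events=int(datasets[0]["event"].sum()))
    return report, curves
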