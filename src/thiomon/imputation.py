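"""Multiple imputation by chained equations with Rubin's-rules pooling.

Missing BMI, alcohol and mercaptopurine-equivalent dose are imputed with
chained conditional models that include every candidate predictor, the
Nelson-Aalen cumulative hazard evaluated at each subject's exit time, and
the event indicator — the standard recipe for survival outcomes. Continuous
fields use predictive-mean matching with Bayesian parameter draws (plain
normal draws as an option); the alcohol category uses a multinomial
logistic model refit on a bootstrap of the observed rows, which
approximates drawing the model parameters from their posterior.

Analysis across imputations is fit-per-dataset-then-pool: each completed
dataset is analysed separately and estimates are combined by Rubin's rules.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .cohort import to_design_matrix
from .risk_model import PARAMETERS

__all__ = [
    "ImputedStack",
    "PooledEstimate",
    "nelson_aalen_hazard",
    "mice_impute",
    "rubin_pool",
]

_IMPUTABLE = ("bmi", "alcohol", "mp_equiv_dose")
_ALCOHOL_LEVELS = ("none", "low", "moderate", "hazardous", "ex")


def nelson_aalen_hazard(times: np.ndarray, events: np.ndarray) -> np.ndarray:
    """Nelson-Aalen cumulative hazard at each subject's own exit time.

    H(t) = sum over observed event times t_j <= t of d_j / n_j, where d_j is
    the number of events at t_j and n_j the number at risk.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    order = np.argsort(times, kind="stable")
    ts, es = times[order], events[order]
    n = ts.size
    ev_times = np.unique(ts[es == 1])
    if ev_times.size == 0:
        return np.zeros(n)
    d = np.array([(ts[es == 1] == t).sum() for t in ev_times])
    at_risk = n - np.searchsorted(ts, ev_times, side="left")
    H_steps = np.cumsum(d / at_risk)
    idx = np.searchsorted(ev_times, times, side="right")
    return np.where(idx > 0, H_steps[np.maximum(idx - 1, 0)], 0.0)


@dataclass
class ImputedStack:
    """m completed copies of a cohort; only originally-missing cells differ."""

    datasets: list[pd.DataFrame]
    seed: int
    iterations: int

    @property
    def m(self) -> int:
        return len(self.datasets)


@dataclass
class PooledEstimate:
    estimate: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    ci95: tuple[float, float]

    @property
    def se(self) -> float:
        return math.sqrt(self.total_var)


def rubin_pool(estimates, variances) -> PooledEstimate:
    """Combine per-imputation estimates and variances by Rubin's rules."""
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape:
        raise ValueError("estimates and variances have mismatched lengths")
    m = q.size
    if m < 2:
        raise ValueError("pooling requires at least two imputations")
    if np.any(u < 0):
        raise ValueError("variances must be non-negative")
    qbar = float(q.mean())
    within = float(u.mean())
    between = float(q.var(ddof=1))
    total = within + (1.0 + 1.0 / m) * between
    if between > 0:
        r = (1.0 + 1.0 / m) * between / within if within > 0 else np.inf
        df = (m - 1) * (1.0 + 1.0 / r) ** 2 if np.isfinite(r) and r > 0 else m - 1.0
    else:
        df = np.inf
    tcrit = stats.t.ppf(0.975, df) if np.isfinite(df) else stats.norm.ppf(0.975)
    half = tcrit * math.sqrt(total)
    return PooledEstimate(qbar, within, between, total, float(df),
                          (qbar - half, qbar + half))


def _conditional_design(completed: pd.DataFrame, target: str,
                        na_hazard: np.ndarray) -> np.ndarray:
    """Covariate matrix for one conditional model: all candidate predictors
    except the target's own coding, plus the cumulative hazard and event."""
    design = to_design_matrix(completed)
    drop = {"bmi": ["bmi"], "mp_equiv_dose": ["mp_equiv_dose"],
            "alcohol": ["alcohol_low", "alcohol_moderate",
                        "alcohol_hazardous", "alcohol_ex"]}[target]
    cols = [p for p in PARAMETERS if p not in drop]
    X = design[cols].to_numpy(dtype=float)
    return np.column_stack([X, na_hazard, completed["event"].to_numpy(dtype=float)])


def _bayes_linear_draw(Xo, yo, rng):
    """Posterior draw of (beta, sigma) under the noninformative prior."""
    n, p = Xo.shape
    Xd = np.column_stack([np.ones(n), Xo])
    XtX = Xd.T @ Xd + 1e-8 * np.eye(p + 1)
    beta_hat = np.linalg.solve(XtX, Xd.T @ yo)
    resid = yo - Xd @ beta_hat
    dof = max(n - p - 1, 2)
    sigma2 = resid @ resid / rng.chisquare(dof)
    L = np.linalg.cholesky(np.linalg.inv(XtX))
    beta_draw = beta_hat + math.sqrt(sigma2) * (L @ rng.standard_normal(p + 1))
    return Xd, beta_hat, beta_draw, math.sqrt(sigma2)


def _impute_continuous(completed, target, obs_mask, na_hazard, rng,
                       method="pmm", donors=5):
    X = _conditional_design(completed, target, na_hazard)
    y = completed[target].to_numpy(dtype=float)
    Xo, yo = X[obs_mask], y[obs_mask]
    Xd_o, beta_hat, beta_draw, sigma = _bayes_linear_draw(Xo, yo, rng)
    Xd_m = np.column_stack([np.ones((~obs_mask).sum()), X[~obs_mask]])
    if method == "norm":
        return Xd_m @ beta_draw + sigma * rng.standard_normal(Xd_m.shape[0])
    # type-1 predictive-mean matching: observed predictions with the ML fit,
    # missing predictions with the parameter draw
    pred_obs = Xd_o @ beta_hat
    pred_mis = Xd_m @ beta_draw
    order = np.argsort(pred_obs, kind="stable")
    pred_sorted = pred_obs[order]
    out = np.empty(pred_mis.size)
    k = min(donors, yo.size)
    for i, pm in enumerate(pred_mis):
        j = np.searchsorted(pred_sorted, pm)
        lo, hi = max(0, j - k), min(yo.size, j + k)
        cand = order[lo:hi]
        nearest = cand[np.argsort(np.abs(pred_obs[cand] - pm), kind="stable")[:k]]
        out[i] = yo[nearest[rng.integers(0, nearest.size)]]
    return out


def _impute_alcohol(completed, obs_mask, na_hazard, rng):
    X = _conditional_design(completed, "alcohol", na_hazard)
    y = completed["alcohol"].to_numpy()
    Xo, yo = X[obs_mask], y[obs_mask]
    # bootstrap the observed rows before fitting as an approximate
    # posterior draw of the multinomial-logistic parameters
    boot = rng.integers(0, Xo.shape[0], Xo.shape[0])
    clf = LogisticRegression(max_iter=500, C=1e4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(Xo[boot], yo[boot])
    proba = clf.predict_proba(X[~obs_mask])
    cum = np.cumsum(proba, axis=1)
    u = rng.random(proba.shape[0])
    picks = (u[:, None] > cum).sum(axis=1)
    return np.asarray(clf.classes_)[picks]


def mice_impute(
    cohort: pd.DataFrame,
    m: int = 10,
    iterations: int = 10,
    seed: int = 0,
    method: str = "pmm",
) -> ImputedStack:
    """Chained-equation multiple imputation of BMI, alcohol and dose.

    Visit order is ascending missingness. Observed cells are never altered;
    each of the m completed datasets uses an independent substream spawned
    from the master seed, so results are reproducible and the first m' < m
    datasets of a larger run coincide with an m'-imputation run.
    """
    if m < 2:
        raise ValueError("m must be at least 2")
    other = [c for c in cohort.columns if c not in _IMPUTABLE]
    if cohort[other].isna().any().any():
        bad = cohort[other].columns[cohort[other].isna().any()].tolist()
        raise ValueError(f"missingness only supported in {_IMPUTABLE}; found in {bad}")

    miss = {f: cohort[f].isna().to_numpy() for f in _IMPUTABLE}
    targets = [f for f in _IMPUTABLE if miss[f].any()]
    if not targets:
        return ImputedStack([cohort.copy() for _ in range(m)], seed, iterations)
    targets.sort(key=lambda f: miss[f].sum())  # ascending missingness

    na_hazard = nelson_aalen_hazard(cohort["followup_time"].to_numpy(),
                                    cohort["event"].to_numpy())
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(m)]

    datasets = []
    for rng in streams:
        completed = cohort.copy()
        # initialise missing cells with random draws from the observed values
        for f in targets:
            obs_vals = cohort.loc[~miss[f], f].to_numpy()
            completed.loc[miss[f], f] = obs_vals[rng.integers(0, obs_vals.size,
                                                              miss[f].sum())]
        for _ in range(iterations):
            for f in targets:
                obs = ~miss[f]
                if f == "alcohol":
                    completed.loc[miss[f], f] = _impute_alcohol(
                        completed, obs, na_hazard, rng)
                else:
                    completed.loc[miss[f], f] = _impute_continuous(
                        completed, f, obs, na_hazard, rng, method=method)
        datasets.append(completed)
    return ImputedStack(datasets, seed, iterations)
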