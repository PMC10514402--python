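"""Internal Cox partial-likelihood machinery.

A lean, vectorised Newton-Raphson solver for the Cox proportional-hazards
partial likelihood with Efron tie handling, plus a Breslow-type baseline
cumulative hazard referenced to the all-zero covariate profile.

The pipeline refits the same model thousands of times during bootstrap
internal validation and computes many univariate fits for the calibration
slope and Royston D; this module keeps those loops fast. The development
module's reference multivariable fit goes through lifelines, which also
serves as the cross-check for this solver in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CoxFit", "cox_fit", "breslow_cumhaz"]

# linear predictors are clipped before exponentiation so monotone-likelihood
# resamples overflow gracefully instead of producing NaNs
_ETA_CLIP = 200.0


@dataclass
class CoxFit:
    """Result of a partial-likelihood fit."""

    beta: np.ndarray          # (p,) coefficient estimates
    cov: np.ndarray           # (p, p) inverse observed information
    loglik: float
    converged: bool
    n_iter: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def _efron_quantities(X, t, e, eta):
    """Log-likelihood, score and observed information under Efron ties.

    Inputs must be sorted by ascending time. Returns (ll, grad, info).
    """
    n, p = X.shape
    theta = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
    M = theta[:, None] * X                      # (n, p)
    B = X[:, :, None] * M[:, None, :]           # (n, p, p) theta * x x'

    # suffix (risk-set) sums: entry i covers subjects with index >= i
    s0_suf = np.cumsum(theta[::-1])[::-1]
    s1_suf = np.cumsum(M[::-1], axis=0)[::-1]
    s2_suf = np.cumsum(B[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))

    event_idx = np.flatnonzero(e == 1)
    if event_idx.size == 0:
        return ll, grad, info
    ev_times = t[event_idx]
    # boundaries between distinct event times
    cuts = np.flatnonzero(np.diff(ev_times) > 0)
    group_starts = np.concatenate(([0], cuts + 1))
    group_ends = np.concatenate((cuts + 1, [event_idx.size]))

    for a, b in zip(group_starts, group_ends):
        D = event_idx[a:b]
        tau = t[D[0]]
        d = D.size
        i0 = np.searchsorted(t, tau, side="left")
        s0, s1, s2 = s0_suf[i0], s1_suf[i0], s2_suf[i0]
        d0 = theta[D].sum()
        d1 = M[D].sum(axis=0)
        d2 = B[D].sum(axis=0)

        frac = np.arange(d) / d                  # Efron fractions l/d
        den = s0 - frac * d0                     # (d,)
        z1 = s1[None, :] - frac[:, None] * d1[None, :]          # (d, p)
        z2 = s2[None, :, :] - frac[:, None, None] * d2[None, :, :]

        ll += eta[D].sum() - np.log(den).sum()
        w1 = z1 / den[:, None]
        grad += X[D].sum(axis=0) - w1.sum(axis=0)
        info += (z2 / den[:, None, None]).sum(axis=0) - w1.T @ w1
    return ll, grad, info


def cox_fit(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    offset: np.ndarray | None = None,
    ridge: float = 0.0,
    max_iter: int = 60,
    tol: float = 1e-9,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Parameters
    ----------
    X
        (n, p) covariate matrix. Columns must have non-zero variance among
        subjects at risk (callers drop degenerate columns).
    time, event
        Follow-up times (> 0) and 0/1 event indicators.
    offset
        Optional fixed addition to the linear predictor (used when
        re-estimating the baseline under a shrunken, frozen predictor).
    ridge
        Small L2 penalty on the coefficients; 0 gives the plain partial
        likelihood.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n, p = X.shape
    if time.shape != (n,) or event.shape != (n,):
        raise ValueError("X, time and event have mismatched lengths")
    if event.sum() == 0:
        raise ValueError("cannot fit a Cox model with zero events")
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)

    order = np.argsort(time, kind="stable")
    Xs, ts, es, offs = X[order], time[order], event[order], off[order]

    beta = np.zeros(p)
    ll_prev = -np.inf
    converged = False
    it = 0
    ll, grad, info = -np.inf, np.zeros(p), np.eye(p)
    for it in range(1, max_iter + 1):
        eta = Xs @ beta + offs
        ll, grad, info = _efron_quantities(Xs, ts, es, eta)
        if ridge > 0:
            ll -= 0.5 * ridge * beta @ beta
            grad = grad - ridge * beta
            info = info + ridge * np.eye(p)
        if not np.isfinite(ll):
            break
        if ll < ll_prev - 1e-10:
            # step-halve back toward the previous iterate
            beta = 0.5 * (beta + beta_prev)
            continue
        if abs(ll - ll_prev) < tol * (abs(ll) + 1.0):
            converged = True
            break
        ll_prev = ll
        beta_prev = beta.copy()
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)) or np.max(np.abs(step)) > 50:
            break  # monotone likelihood / separation
        beta = beta + step

    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    if not np.all(np.isfinite(beta)) or not np.isfinite(ll):
        converged = False
    return CoxFit(beta=beta, cov=cov, loglik=float(ll), converged=converged, n_iter=it)


def breslow_cumhaz(
    time: np.ndarray,
    event: np.ndarray,
    eta: np.ndarray,
    eval_times: np.ndarray,
) -> np.ndarray:
    """Breslow baseline cumulative hazard at the all-zero covariate profile.

    ``eta`` is the full linear predictor (coefficients times covariates plus
    any offset) for each subject; the baseline refers to eta = 0.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    eta = np.asarray(eta, dtype=float)
    order = np.argsort(time, kind="stable")
    ts, es = time[order], event[order]
    theta = np.exp(np.clip(eta[order], -_ETA_CLIP, _ETA_CLIP))
    s0_suf = np.cumsum(theta[::-1])[::-1]

    ev = np.flatnonzero(es == 1)
    if ev.size == 0:
        return np.zeros(np.shape(eval_times))
    ev_times, first = np.unique(ts[ev], return_index=True)
    d = np.bincount(np.searchsorted(ev_times, ts[ev]))
    denom = s0_suf[np.searchsorted(ts, ev_times, side="left")]
    increments = d / denom
    H = np.cumsum(increments)
    idx = np.searchsorted(ev_times, np.asarray(eval_times, dtype=float), side="right")
    out = np.where(idx > 0, H[np.maximum(idx - 1, 0)], 0.0)
    return out
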