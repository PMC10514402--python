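"""Model development: pooled Cox fit, baseline survival, functional-form and
proportional-hazards checks, and minimum-sample-size criteria.

The development fit keeps all candidate predictors (no variable selection),
estimates each coefficient per completed dataset with Efron tie handling and
pools across imputations by Rubin's rules. The baseline survival S0(t) is a
Breslow-type estimate referenced to the all-zero covariate profile — the
reference needed for the published risk equation 1 - S0(t)^exp(beta.X) to
be interpretable as written — averaged over imputations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import proportional_hazard_test
from scipy import stats

from ._cox import breslow_cumhaz, cox_fit
from .cohort import to_design_matrix
from .imputation import ImputedStack, PooledEstimate, rubin_pool
from .risk_model import PARAMETERS, PublishedModel

__all__ = [
    "CoxModelFit",
    "SampleSizeSpec",
    "RileyResult",
    "FPDecision",
    "PHCheckResult",
    "fit_pooled_cox",
    "baseline_survival",
    "fp1_vs_linear",
    "ph_check",
    "riley_min_sample_size",
    "crude_incidence_per_1000py",
    "event_fraction_percent",
]

FP1_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


# ---------------------------------------------------------------------------
# simple cohort summaries

def crude_incidence_per_1000py(events: float, person_years: float) -> float:
    """Crude incidence rate per 1000 person-years."""
    if person_years <= 0:
        raise ValueError("person-years must be positive")
    return 1000.0 * events / person_years


def event_fraction_percent(events: float, n: float) -> float:
    """Percentage of subjects with the outcome."""
    if n <= 0:
        raise ValueError("n must be positive")
    return 100.0 * events / n


# ---------------------------------------------------------------------------
# pooled Cox development fit

@dataclass
class CoxModelFit:
    """A (possibly shrunken) Cox model with its baseline survival."""

    coefficients: dict[str, float]
    covariance: pd.DataFrame
    s0: dict[float, float] = field(default_factory=dict)  # horizon -> S0
    shrinkage: float = 1.0
    n: int = 0
    events: int = 0
    pooled: dict[str, PooledEstimate] = field(default_factory=dict)

    @property
    def parameters(self) -> list[str]:
        return list(self.coefficients)

    def linear_predictor(self, design: pd.DataFrame) -> np.ndarray:
        """Unshrunken beta.X for a design-matrix cohort."""
        X = design[self.parameters].to_numpy(dtype=float)
        beta = np.array([self.coefficients[p] for p in self.parameters])
        return X @ beta

    def as_scoring_rule(self, horizon: float = 5.0) -> PublishedModel:
        """Expose the fitted model through the generic risk-equation
        evaluator (coefficients, shrinkage factor, baseline survival)."""
        if horizon not in self.s0:
            raise ValueError(f"no baseline survival estimated at horizon {horizon}")
        return PublishedModel(coefficients=dict(self.coefficients),
                              shrinkage=self.shrinkage,
                              s0=self.s0[horizon], horizon=horizon)


def _design_stack(stack: ImputedStack) -> list[pd.DataFrame]:
    return [to_design_matrix(d) for d in stack.datasets]


def fit_pooled_cox(
    stack: ImputedStack,
    parameters: list[str] | None = None,
    horizons: tuple[float, ...] = (5.0,),
) -> CoxModelFit:
    """Fit the full Cox model in each completed dataset and Rubin-pool.

    Per-dataset fits use lifelines (Efron ties). The pooled covariance has
    Rubin total variances on the diagonal and the average of within-dataset
    off-diagonal covariances elsewhere (between-imputation off-diagonal
    terms are ignored — a documented approximation).
    """
    parameters = list(parameters or PARAMETERS)
    designs = _design_stack(stack)
    betas, covs = [], []
    for i, design in enumerate(designs):
        data = design[parameters + ["followup_time", "event"]]
        if data.isna().any().any():
            raise ValueError(f"imputed dataset {i} still contains missing values")
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(data, duration_col="followup_time", event_col="event")
        except Exception as exc:  # noqa: BLE001 - report which dataset failed
            raise RuntimeError(f"Cox fit failed to converge in imputed dataset {i}: {exc}")
        betas.append(cph.params_[parameters])
        covs.append(cph.variance_matrix_.loc[parameters, parameters])

    pooled = {p: rubin_pool([b[p] for b in betas], [c.loc[p, p] for c in covs])
              for p in parameters}
    cov = sum(c.to_numpy() for c in covs) / len(covs)
    np.fill_diagonal(cov, [pooled[p].total_var for p in parameters])
    covariance = pd.DataFrame(cov, index=parameters, columns=parameters)

    fit = CoxModelFit(
        coefficients={p: pooled[p].estimate for p in parameters},
        covariance=covariance,
        n=len(stack.datasets[0]),
        events=int(stack.datasets[0]["event"].sum()),
        pooled=pooled,
    )
    fit.s0 = baseline_survival(fit, stack, list(horizons))
    return fit


def baseline_survival(
    fit: CoxModelFit,
    stack: ImputedStack,
    horizons: list[float],
) -> dict[float, float]:
    """Breslow baseline survival at the all-zero profile, averaged over
    imputations. The (shrunken) linear predictor enters as a fixed offset."""
    H = np.zeros(len(horizons))
    last_event = 0.0
    for design in _design_stack(stack):
        eta = fit.shrinkage * fit.linear_predictor(design)
        t = design["followup_time"].to_numpy(dtype=float)
        e = design["event"].to_numpy(dtype=int)
        if e.sum():
            last_event = max(last_event, t[e == 1].max())
        H += breslow_cumhaz(t, e, eta, np.asarray(horizons, dtype=float))
    H /= len(stack.datasets)
    for h in horizons:
        if h > last_event:
            warnings.warn(f"horizon {h} beyond last event time {last_event:.3f}; "
                          "carrying the last baseline value forward")
    return {h: float(math.exp(-Hh)) for h, Hh in zip(horizons, H)}


# ---------------------------------------------------------------------------
# functional form (first-order fractional polynomials)

@dataclass
class FPDecision:
    decision: str                 # 'linear' or 'FP1'
    power: float                  # best first-order power (1.0 = linear)
    p_value: float                # deviance test of best FP1 vs linear, 1 df
    logliks: dict[float, float]   # mean partial log-likelihood by power
    shift: float


def _fp_transform(x: np.ndarray, power: float) -> np.ndarray:
    z = np.log(x) if power == 0.0 else x ** power
    return (z - z.mean()) / (z.std() + 1e-12)  # scaling leaves the LRT invariant


def fp1_vs_linear(stack: ImputedStack, predictor: str,
                  alpha: float = 0.05) -> FPDecision:
    """Choose between a linear term and the best first-order fractional
    polynomial for a continuous predictor.

    The best FP1 power is picked by mean partial log-likelihood across
    imputations; a 1-df deviance test against the linear term keeps the
    linear form when p > alpha.
    """
    designs = _design_stack(stack)
    xmin = min(d[predictor].min() for d in designs)
    shift = 0.0 if xmin > 0 else -xmin + 1.0  # shift to positivity
    others = [p for p in PARAMETERS if p != predictor]

    logliks = {}
    for power in FP1_POWERS:
        ll = 0.0
        for design in designs:
            x = design[predictor].to_numpy(dtype=float) + shift
            X = np.column_stack([_fp_transform(x, power),
                                 design[others].to_numpy(dtype=float)])
            res = cox_fit(X, design["followup_time"].to_numpy(),
                          design["event"].to_numpy())
            ll += res.loglik
        logliks[power] = ll / len(designs)

    best = max(logliks, key=logliks.get)
    dev = 2.0 * (logliks[best] - logliks[1.0])
    p_value = float(stats.chi2.sf(max(dev, 0.0), 1))
    if best == 1.0 or p_value > alpha:
        return FPDecision("linear", 1.0, p_value, logliks, shift)
    return FPDecision("FP1", best, p_value, logliks, shift)


# ---------------------------------------------------------------------------
# proportional hazards

@dataclass
class PHCheckResult:
    available: bool
    p_values: pd.DataFrame | None        # parameters x imputations
    global_p: float | None               # smallest mean per-parameter p
    loglog_curves: dict[str, pd.DataFrame] = field(default_factory=dict)


def ph_check(stack: ImputedStack, fit: CoxModelFit,
             curve_parameters: tuple[str, ...] = ("prior_mild_abnormality", "ckd3"),
             ) -> PHCheckResult:
    """Schoenfeld-residual correlation test per parameter, per imputation,
    plus log(-log S) curve data for selected binary predictors."""
    parameters = fit.parameters
    pvals = {}
    try:
        for i, design in enumerate(_design_stack(stack)):
            data = design[parameters + ["followup_time", "event"]]
            cph = CoxPHFitter()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(data, "followup_time", "event")
                res = proportional_hazard_test(cph, data, time_transform="rank")
            pvals[i] = res.summary["p"].reindex(parameters)
    except Exception:
        return PHCheckResult(False, None, None)
    ptab = pd.DataFrame(pvals)

    curves = {}
    base = stack.datasets[0]
    design0 = to_design_matrix(base)
    for par in curve_parameters:
        frames = []
        for level in (0, 1):
            sel = design0[par] == level
            if sel.sum() < 2 or design0.loc[sel, "event"].sum() < 1:
                continue
            km = KaplanMeierFitter().fit(design0.loc[sel, "followup_time"],
                                         design0.loc[sel, "event"])
            s = km.survival_function_.iloc[:, 0]
            keep = (s > 0) & (s < 1)
            frames.append(pd.DataFrame({
                "time": s.index[keep], "level": level,
                "loglog_survival": np.log(-np.log(s[keep]))}))
        if frames:
            curves[par] = pd.concat(frames, ignore_index=True)
    return PHCheckResult(True, ptab, float(ptab.mean(axis=1).min()), curves)


# ---------------------------------------------------------------------------
# minimum sample size (shrinkage-based and companion criteria)

@dataclass(frozen=True)
class SampleSizeSpec:
    p: int = 25                    # candidate parameters
    target_shrinkage: float = 0.9
    r2_cs: float = 0.12            # anticipated Cox-Snell R-squared
    event_rate: float = 0.017      # events per person-year
    mean_followup: float = 3.19    # years
    horizon: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_shrinkage < 1.0:
            raise ValueError("target shrinkage must lie in (0, 1)")
        if not 0.0 < self.r2_cs < 1.0:
            raise ValueError("Cox-Snell R-squared must lie in (0, 1)")
        if self.r2_cs >= self.target_shrinkage:
            raise ValueError("r2_cs must be below the target shrinkage "
                             "(log term undefined otherwise)")


@dataclass
class RileyResult:
    n_min: int
    events_min: int
    criteria: dict[str, float]
    binding: str


def riley_min_sample_size(spec: SampleSizeSpec = SampleSizeSpec()) -> RileyResult:
    """Minimum development sample size for a survival prediction model.

    Criterion 1 targets a global shrinkage factor of at least S:
    n = p / ((S - 1) * ln(1 - R2cs / S)). Criterion 2 bounds the optimism
    in apparent R2cs by 0.05, and criterion 3 requires the overall outcome
    proportion at the horizon to be estimated within +/- 0.05. The binding
    (largest) criterion is returned, with the implied event count.
    """
    S, r2, p = spec.target_shrinkage, spec.r2_cs, spec.p
    n1 = p / ((S - 1.0) * math.log(1.0 - r2 / S))
    s2 = r2 / (r2 + 0.05)
    n2 = p / ((s2 - 1.0) * math.log(1.0 - r2 / s2))
    phi = 1.0 - math.exp(-spec.event_rate * spec.horizon)
    n3 = (1.96 / 0.05) ** 2 * phi * (1.0 - phi)
    criteria = {"shrinkage": math.ceil(n1), "r2_optimism": math.ceil(n2),
                "overall_risk_precision": math.ceil(n3)}
    binding = max(criteria, key=criteria.get)
    n_min = int(criteria[binding])
    events_min = math.ceil(n_min * spec.mean_followup * spec.event_rate)
    return RileyResult(n_min, int(events_min), criteria, binding)
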