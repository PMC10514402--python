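"""The published risk equation for thiopurine discontinuation.

Predicts an individual's risk of thiopurine discontinuation associated with
an abnormal monitoring blood test within 5 years of established primary-care
prescribing, from 14 routinely recorded predictors coded as 21 model
parameters. The score is

    risk = 1 - S0(5) ** exp(s * beta.X)

where ``beta.X`` is the linear predictor (log-hazard scale), ``s`` the
uniform shrinkage factor applied to counter overfitting, and ``S0(5)`` the
baseline survival at five years for a subject with every covariate equal to
zero. The published constants are ``s = 0.80`` and ``S0(5) = 0.938``.

Missing predictor values are rejected here: imputation happens upstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PARAMETERS",
    "PUBLISHED_COEFFICIENTS",
    "PredictorProfile",
    "PublishedModel",
    "published_model",
    "linear_predictor",
    "predicted_risk",
    "coefficient_to_hr",
    "hr_to_coefficient",
    "score_cohort",
]

#: The 21 model parameters, in the order the risk equation lists them.
PARAMETERS: tuple[str, ...] = (
    "mp_equiv_dose",
    "age",
    "female",
    "bmi",
    "current_smoker",
    "alcohol_low",
    "alcohol_moderate",
    "alcohol_hazardous",
    "alcohol_ex",
    "ra",
    "sle",
    "seroneg",
    "diabetes",
    "ckd3",
    "five_asa",
    "sulfasalazine",
    "mtx_lef",
    "statin",
    "allopurinol",
    "ace_inhibitor",
    "prior_mild_abnormality",
)

#: Final-model log hazard ratios at full published precision (pre-shrinkage).
PUBLISHED_COEFFICIENTS: dict[str, float] = {
    "mp_equiv_dose": -0.0031592,
    "age": 0.0120654,
    "female": 0.0348383,
    "bmi": 0.0021012,
    "current_smoker": -0.0161052,
    "alcohol_low": -0.0119396,
    "alcohol_moderate": -0.1516204,
    "alcohol_hazardous": 0.215067,
    "alcohol_ex": -0.1501354,
    "ra": 0.4467324,
    "sle": 0.7810266,
    "seroneg": 0.2838247,
    "diabetes": -0.0919595,
    "ckd3": 0.4197865,
    "five_asa": 0.1014151,
    "sulfasalazine": -0.3581131,
    "mtx_lef": -0.1177929,
    "statin": 0.0629356,
    "allopurinol": -0.0473062,
    "ace_inhibitor": 0.0440477,
    "prior_mild_abnormality": 0.9939685,
}

_BINARY = tuple(p for p in PARAMETERS if p not in ("mp_equiv_dose", "age", "bmi"))
_ALCOHOL_DUMMIES = ("alcohol_low", "alcohol_moderate", "alcohol_hazardous", "alcohol_ex")
_DISEASE_DUMMIES = ("ra", "sle", "seroneg")


@dataclass(frozen=True)
class PredictorProfile:
    """One subject's coded covariate vector.

    Binary fields are 0/1 dummies; the inflammatory bowel disease and
    non-drinker / non-current-smoker states are the all-zero references.
    """

    mp_equiv_dose: float = 0.0   # mercaptopurine-equivalent dose, mg/day
    age: float = 0.0             # years at start of follow-up
    female: int = 0
    bmi: float = 0.0             # kg/m^2
    current_smoker: int = 0
    alcohol_low: int = 0
    alcohol_moderate: int = 0
    alcohol_hazardous: int = 0
    alcohol_ex: int = 0
    ra: int = 0
    sle: int = 0
    seroneg: int = 0
    diabetes: int = 0
    ckd3: int = 0
    five_asa: int = 0
    sulfasalazine: int = 0
    mtx_lef: int = 0
    statin: int = 0
    allopurinol: int = 0
    ace_inhibitor: int = 0
    prior_mild_abnormality: int = 0

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if v is None or (isinstance(v, float) and not math.isfinite(v)):
                raise ValueError(f"predictor {f.name!r} is missing or non-finite; "
                                 "impute before scoring")
            if v < 0:
                raise ValueError(f"predictor {f.name!r} must be non-negative")
        if sum(getattr(self, d) for d in _ALCOHOL_DUMMIES) > 1:
            raise ValueError("at most one alcohol dummy may be set")
        if sum(getattr(self, d) for d in _DISEASE_DUMMIES) > 1:
            raise ValueError("at most one disease dummy may be set")
        for b in _BINARY:
            if getattr(self, b) not in (0, 1):
                raise ValueError(f"{b!r} must be 0 or 1")

    def as_vector(self) -> np.ndarray:
        return np.array([float(getattr(self, p)) for p in PARAMETERS])

    @classmethod
    def from_mapping(cls, d: Mapping[str, float]) -> "PredictorProfile":
        unknown = set(d) - set(PARAMETERS)
        if unknown:
            raise ValueError(f"unknown predictor field(s): {sorted(unknown)}")
        return cls(**{k: d[k] for k in d})


@dataclass(frozen=True)
class PublishedModel:
    """A scoring rule: coefficients, shrinkage factor, baseline survival.

    With the default constants this is the published equation; the same
    evaluator is reused by the development pipeline with its own fitted
    coefficients and baseline.
    """

    coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(PUBLISHED_COEFFICIENTS))
    shrinkage: float = 0.80
    s0: float = 0.938            # baseline survival at the horizon
    horizon: float = 5.0         # years

    def __post_init__(self) -> None:
        if not 0.0 < self.s0 < 1.0:
            raise ValueError("baseline survival must lie in (0, 1)")
        if not 0.0 < self.shrinkage <= 1.5:
            raise ValueError("shrinkage factor out of range")
        missing = set(self.coefficients) - set(PARAMETERS)
        if missing:
            raise ValueError(f"unknown coefficient name(s): {sorted(missing)}")


def published_model() -> PublishedModel:
    """The risk equation with the published constants."""
    return PublishedModel()


def linear_predictor(profile: PredictorProfile, model: PublishedModel | None = None) -> float:
    """Unshrunken linear predictor beta.X on the log-hazard scale."""
    model = model or published_model()
    return float(sum(model.coefficients.get(p, 0.0) * float(getattr(profile, p))
                     for p in PARAMETERS))


def predicted_risk(profile: PredictorProfile, model: PublishedModel | None = None) -> float:
    """Absolute risk of discontinuation by the model horizon.

    1 - S0 ** exp(shrinkage * beta.X); strictly inside (0, 1) and monotone
    increasing in the linear predictor.
    """
    model = model or published_model()
    bx = linear_predictor(profile, model)
    return risk_from_lp(bx, model)


def risk_from_lp(bx: float | np.ndarray, model: PublishedModel | None = None):
    """Vectorisable form of the risk equation given precomputed beta.X."""
    model = model or published_model()
    return 1.0 - model.s0 ** np.exp(model.shrinkage * np.asarray(bx, dtype=float))


def coefficient_to_hr(beta: float) -> float:
    """Hazard ratio implied by a log hazard ratio."""
    if not math.isfinite(beta):
        raise ValueError("coefficient must be finite")
    return math.exp(beta)


def hr_to_coefficient(hr: float) -> float:
    if hr <= 0:
        raise ValueError("hazard ratio must be positive")
    return math.log(hr)


def score_cohort(cohort: pd.DataFrame, model: PublishedModel | None = None) -> pd.DataFrame:
    """Score a design-matrix cohort (one column per model parameter).

    Returns a copy with ``linear_predictor`` and ``predicted_risk`` columns.
    Missing predictor cells are rejected.
    """
    model = model or published_model()
    missing_cols = [p for p in PARAMETERS if p not in cohort.columns]
    if missing_cols:
        raise ValueError(f"cohort lacks predictor column(s): {missing_cols}")
    X = cohort[list(PARAMETERS)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("cohort contains missing predictor values; impute first")
    beta = np.array([model.coefficients.get(p, 0.0) for p in PARAMETERS])
    out = cohort.copy()
    out["linear_predictor"] = X @ beta
    out["predicted_risk"] = risk_from_lp(out["linear_predictor"].to_numpy(), model)
    return out
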