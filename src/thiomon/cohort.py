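"""Synthetic CPRD-like cohorts and longitudinal outcome ascertainment.

Real primary-care records of thiopurine users cannot be redistributed, so
this module generates cohorts with the statistical structure the analysis
assumes: marginal predictor distributions matching the published development
cohort, event times from a proportional-hazards model with a constant
baseline hazard, competing exponential censoring clocks (transfer out of
practice, a 90-day prescription gap without abnormality, death at a
negligible rate) plus administrative censoring at five years, and
missingness injected into BMI, alcohol and dose at the observed rates.

It also implements the deterministic rules that turn longitudinal
prescription/laboratory streams into the analysis dataset: the
abnormal-blood-test thresholds, the prescription-gap outcome definition and
the predictor look-back windows.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .risk_model import PARAMETERS, PUBLISHED_COEFFICIENTS

__all__ = [
    "ConfigurationError",
    "CohortMarginals",
    "TrueModel",
    "PrescriptionEvent",
    "LabResult",
    "CodedEvent",
    "OutcomeResult",
    "default_true_model",
    "generate_cohort",
    "to_design_matrix",
    "classify_abnormal",
    "ascertain_outcome",
    "derive_predictors",
    "mp_equivalent_dose",
    "AZATHIOPRINE_TO_MP",
    "TWO_YEARS_DAYS",
    "SIX_MONTHS_DAYS",
]


class ConfigurationError(ValueError):
    """Invalid simulation or model configuration."""


# ---------------------------------------------------------------------------
# dose conversion

#: mg mercaptopurine-equivalent per mg azathioprine (100 mg/day -> 48.1 mg/day)
AZATHIOPRINE_TO_MP = 0.481


def mp_equivalent_dose(drug: str, dose: float, conversion: float = AZATHIOPRINE_TO_MP) -> float:
    """Mercaptopurine-equivalent daily dose in mg/day."""
    if dose <= 0:
        raise ValueError("dose must be positive")
    if drug == "mercaptopurine":
        return float(dose)
    if drug == "azathioprine":
        return float(dose) * conversion
    raise ValueError(f"unknown thiopurine {drug!r}")


# ---------------------------------------------------------------------------
# abnormal blood-test thresholds

# outcome-grade: the abnormalities that qualify a discontinuation as the event
_OUTCOME_LOW = {"wbc": 3.5, "neutrophils": 1.6, "platelets": 140.0}
_OUTCOME_HIGH = {"alt": 100.0, "ast": 100.0}
# mild-grade: the "at least mild cytopenia or liver enzyme elevation" predictor
_MILD_LOW = {"wbc": 4.0, "neutrophils": 2.0, "platelets": 150.0}
_MILD_HIGH = {"alt": 35.0, "ast": 35.0}

_CREATININE_RISE = 26.0  # umol/l rise vs the subject's preceding value

ANALYTES = ("wbc", "neutrophils", "platelets", "alt", "ast", "creatinine")


def classify_abnormal(
    analyte: str,
    value: float,
    context: str = "outcome",
    previous_value: float | None = None,
) -> bool:
    """Flag a laboratory result as abnormal.

    ``context='outcome'`` applies the outcome-grade thresholds (strict
    inequalities as published); ``context='prior_mild'`` the mild-grade
    thresholds used for the prior-abnormality predictor. Creatinine is
    handled only in the outcome context, as a rise of more than 26 umol/l
    relative to the subject's preceding value.
    """
    if analyte not in ANALYTES:
        raise ValueError(f"unknown analyte {analyte!r}")
    if context not in ("outcome", "prior_mild"):
        raise ValueError(f"unknown context {context!r}")
    if analyte == "creatinine":
        if context != "outcome" or previous_value is None:
            return False
        return value - previous_value > _CREATININE_RISE
    low = _OUTCOME_LOW if context == "outcome" else _MILD_LOW
    high = _OUTCOME_HIGH if context == "outcome" else _MILD_HIGH
    if analyte in low:
        return value < low[analyte]
    return value > high[analyte]


# ---------------------------------------------------------------------------
# longitudinal record types

@dataclass(frozen=True)
class PrescriptionEvent:
    subject_id: str
    date: int                    # days from registration
    drug: str                    # azathioprine | mercaptopurine | other
    dose_mg_day: float = 0.0


@dataclass(frozen=True)
class LabResult:
    subject_id: str
    date: int
    analyte: str
    value: float


@dataclass(frozen=True)
class CodedEvent:
    """An opaque diagnostic code; ``qualifying`` marks codes that count
    toward the outcome (e.g. recorded CKD progression)."""

    subject_id: str
    date: int
    qualifying: bool = False


@dataclass(frozen=True)
class OutcomeResult:
    event: int
    event_time: float            # years from follow-up start to exit
    reason: str                  # event | gap_no_abnormality | admin_end | ...


DAYS_PER_YEAR = 365.25
GAP_DAYS = 90                    # prescription gap defining discontinuation
WINDOW_DAYS = 60                 # +/- window around the last prescription
TWO_YEARS_DAYS = 730             # clinical-covariate look-back
SIX_MONTHS_DAYS = 183            # prescription / prior-abnormality look-back


def _outcome_abnormality_dates(labs: Sequence[LabResult]) -> list[int]:
    """Dates of outcome-grade abnormalities, with creatinine compared to the
    subject's latest preceding creatinine."""
    labs = sorted(labs, key=lambda r: r.date)
    dates: list[int] = []
    prev_creat: float | None = None
    for r in labs:
        if r.analyte == "creatinine":
            if classify_abnormal("creatinine", r.value, "outcome", prev_creat):
                dates.append(r.date)
            prev_creat = r.value
        elif classify_abnormal(r.analyte, r.value, "outcome"):
            dates.append(r.date)
    return dates


def ascertain_outcome(
    prescriptions: Sequence[PrescriptionEvent],
    labs: Sequence[LabResult],
    codes: Sequence[CodedEvent],
    followup_start: int,
    followup_end: int,
    end_reason: str = "admin_end",
) -> OutcomeResult:
    """Apply the discontinuation-with-abnormality outcome definition.

    The event requires a prescription gap of at least 90 days (between
    consecutive prescriptions, or after the final prescription up to
    ``followup_end``) together with an outcome-grade abnormal blood test or
    a qualifying diagnostic code within +/- 60 days of the last prescription
    date before the gap. The event time is anchored to that last
    prescription date. Gaps anchored before ``followup_start`` reflect
    pre-follow-up history and are ignored.
    """
    if len(prescriptions) == 0:
        raise ValueError("empty prescription stream")
    if followup_start >= followup_end:
        raise ValueError("followup_start must precede followup_end")
    dates = [p.date for p in prescriptions]
    if any(b < a for a, b in zip(dates, dates[1:])):
        raise ValueError("prescriptions must be sorted by date")

    abnormal_dates = _outcome_abnormality_dates(labs)
    code_dates = [c.date for c in codes if c.qualifying]
    marker_dates = sorted(abnormal_dates + code_dates)

    in_window = [d for d in dates if d <= followup_end]
    gap_anchors = [a for a, b in zip(in_window, in_window[1:]) if b - a >= GAP_DAYS]
    if in_window and followup_end - in_window[-1] >= GAP_DAYS:
        gap_anchors.append(in_window[-1])

    for anchor in sorted(gap_anchors):
        if anchor < followup_start:
            continue
        qualifies = any(abs(m - anchor) <= WINDOW_DAYS for m in marker_dates)
        t = (anchor - followup_start) / DAYS_PER_YEAR
        if qualifies:
            return OutcomeResult(1, t, "event")
        return OutcomeResult(0, t, "gap_no_abnormality")
    t_end = (followup_end - followup_start) / DAYS_PER_YEAR
    return OutcomeResult(0, t_end, end_reason)


_DRUG_FLAG_FIELDS = ("five_asa", "sulfasalazine", "mtx_lef", "statin",
                     "allopurinol", "ace_inhibitor")
_CLINICAL_FIELDS = ("bmi", "smoker", "alcohol", "diabetes", "ckd3")


def derive_predictors(
    observations: pd.DataFrame,
    prescriptions: pd.DataFrame,
    labs: Sequence[LabResult],
    index_date: int,
) -> dict:
    """Derive the covariate vector at the start of follow-up.

    Clinical covariates take the latest record in the two years up to and
    including ``index_date`` (window open on the far side); drug flags are
    set by any prescription in the preceding six months; the
    prior-mild-abnormality flag by any mild-grade abnormality in the
    preceding six months. Absent records yield missing values for clinical
    covariates and False for flags.

    ``observations`` columns: date, field, value. ``prescriptions``
    columns: date, category[, drug, dose_mg_day].
    """
    out: dict = {}
    for f in _CLINICAL_FIELDS:
        rows = observations[(observations["field"] == f)
                            & (observations["date"] > index_date - TWO_YEARS_DAYS)
                            & (observations["date"] <= index_date)]
        out[f] = rows.sort_values("date").iloc[-1]["value"] if len(rows) else None

    recent = prescriptions[(prescriptions["date"] > index_date - SIX_MONTHS_DAYS)
                           & (prescriptions["date"] <= index_date)]
    for f in _DRUG_FLAG_FIELDS:
        out[f] = bool((recent["category"] == f).any())

    thio = recent[recent["category"] == "thiopurine"]
    if len(thio):
        last = thio.sort_values("date").iloc[-1]
        out["mp_equiv_dose"] = mp_equivalent_dose(last["drug"], last["dose_mg_day"])
    else:
        out["mp_equiv_dose"] = None

    out["prior_mild_abnormality"] = any(
        index_date - SIX_MONTHS_DAYS < r.date <= index_date
        and classify_abnormal(r.analyte, r.value, "prior_mild")
        for r in labs if r.analyte != "creatinine"
    )
    return out


# ---------------------------------------------------------------------------
# cohort generation

def _norm(counts: Sequence[float]) -> tuple[float, ...]:
    tot = float(sum(counts))
    return tuple(c / tot for c in counts)


@dataclass(frozen=True)
class CohortMarginals:
    """Marginal predictor distributions of the development cohort.

    Categorical proportions are renormalised over non-missing records; the
    missingness rates themselves live on :class:`TrueModel`. BMI is drawn by
    sampling the published category and then uniformly within its band —
    crude within bands, but it reproduces the category frequencies exactly.
    """

    age_mean: float = 42.0
    age_sd: float = 17.0
    age_min: float = 18.0
    age_max: float = 95.0
    p_female: float = 0.509
    # common azathioprine doses (50-200 mg/day) in mercaptopurine equivalents,
    # weighted to match the published median 48.1 and IQR (36.1, 72.1)
    dose_levels: tuple[float, ...] = (24.05, 36.075, 48.1, 72.15, 96.2)
    dose_probs: tuple[float, ...] = (0.15, 0.15, 0.30, 0.25, 0.15)
    bmi_bands: tuple[tuple[float, float], ...] = (
        (16.0, 18.5), (18.5, 25.0), (25.0, 30.0), (30.0, 45.0))
    bmi_probs: tuple[float, ...] = _norm((276, 2178, 1562, 1155))
    p_smoker: float = 0.164
    alcohol_levels: tuple[str, ...] = ("none", "low", "moderate", "hazardous", "ex")
    alcohol_probs: tuple[float, ...] = _norm((1106, 2273, 293, 374, 500))
    disease_levels: tuple[str, ...] = ("IBD", "RA", "SLE", "seroneg_spond")
    disease_probs: tuple[float, ...] = _norm((5317, 230, 243, 192))
    p_diabetes: float = 457 / 5982
    p_ckd3: float = 249 / 5982
    p_five_asa: float = 2766 / 5982
    p_sulfasalazine: float = 74 / 5982
    p_mtx_lef: float = 13 / 5982
    p_statin: float = 645 / 5982
    p_allopurinol: float = 160 / 5982
    p_ace_inhibitor: float = 486 / 5982
    p_prior_mild: float = 785 / 5982

    def __post_init__(self) -> None:
        for name, probs in (("dose_probs", self.dose_probs),
                            ("bmi_probs", self.bmi_probs),
                            ("alcohol_probs", self.alcohol_probs),
                            ("disease_probs", self.disease_probs)):
            if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
                raise ConfigurationError(f"{name} must be non-negative and sum to 1")
        for name in ("p_female", "p_smoker", "p_diabetes", "p_ckd3", "p_five_asa",
                     "p_sulfasalazine", "p_mtx_lef", "p_statin", "p_allopurinol",
                     "p_ace_inhibitor", "p_prior_mild"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class TrueModel:
    """Generating mechanism for synthetic cohorts.

    Event times follow an exponential distribution with rate
    ``baseline_hazard_scale * exp(beta.X)``; censoring comes from
    independent exponential clocks plus the five-year administrative cut.
    """

    coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(PUBLISHED_COEFFICIENTS))
    baseline_hazard_scale: float = 0.0128        # events per person-year at X = 0
    censoring_rates: Mapping[str, float] = field(default_factory=lambda: {
        "transfer_out": 0.056, "rx_gap": 0.198, "death": 0.00025})
    missingness: Mapping[str, float] = field(default_factory=lambda: {
        "bmi": 811 / 5982, "alcohol": 1436 / 5982, "mp_equiv_dose": 627 / 5982})
    admin_horizon: float = 5.0

    def __post_init__(self) -> None:
        if self.baseline_hazard_scale <= 0:
            raise ConfigurationError("baseline_hazard_scale must be positive")
        if any(r < 0 for r in self.censoring_rates.values()):
            raise ConfigurationError("censoring rates must be non-negative")
        bad = {k: v for k, v in self.missingness.items() if not 0.0 <= v < 1.0}
        if bad:
            raise ConfigurationError(f"missingness proportions outside [0, 1): {bad}")
        unknown = set(self.missingness) - {"bmi", "alcohol", "mp_equiv_dose"}
        if unknown:
            raise ConfigurationError(f"missingness not supported for: {sorted(unknown)}")

    def baseline_survival(self, t: float) -> float:
        """Analytic all-zero-covariate survival S0(t) of the generator."""
        return math.exp(-self.baseline_hazard_scale * t)


def _draw_predictors(n: int, marginals: CohortMarginals, rng: np.random.Generator) -> pd.DataFrame:
    m = marginals
    a, b = (m.age_min - m.age_mean) / m.age_sd, (m.age_max - m.age_mean) / m.age_sd
    age = stats.truncnorm.rvs(a, b, loc=m.age_mean, scale=m.age_sd, size=n, random_state=rng)
    sex = np.where(rng.random(n) < m.p_female, "female", "male")
    dose = rng.choice(np.asarray(m.dose_levels), size=n, p=np.asarray(m.dose_probs))
    band = rng.choice(len(m.bmi_bands), size=n, p=np.asarray(m.bmi_probs))
    lo = np.array([m.bmi_bands[i][0] for i in band])
    hi = np.array([m.bmi_bands[i][1] for i in band])
    bmi = lo + rng.random(n) * (hi - lo)
    smoker = np.where(rng.random(n) < m.p_smoker, "current", "not-current")
    alcohol = rng.choice(np.asarray(m.alcohol_levels), size=n, p=np.asarray(m.alcohol_probs))
    disease = rng.choice(np.asarray(m.disease_levels), size=n, p=np.asarray(m.disease_probs))
    df = pd.DataFrame({
        "age": age, "sex": sex, "mp_equiv_dose": dose.astype(float), "bmi": bmi,
        "smoker": smoker, "alcohol": alcohol, "disease": disease,
    })
    for col, p in (("diabetes", m.p_diabetes), ("ckd3", m.p_ckd3),
                   ("five_asa", m.p_five_asa), ("sulfasalazine", m.p_sulfasalazine),
                   ("mtx_lef", m.p_mtx_lef), ("statin", m.p_statin),
                   ("allopurinol", m.p_allopurinol), ("ace_inhibitor", m.p_ace_inhibitor),
                   ("prior_mild_abnormality", m.p_prior_mild)):
        df[col] = (rng.random(n) < p).astype(int)
    return df


def to_design_matrix(cohort: pd.DataFrame) -> pd.DataFrame:
    """Code a subject-record cohort into the 21 model parameters.

    Missing BMI/dose propagate as NaN; a missing alcohol category yields NaN
    in all four alcohol dummies.
    """
    out = pd.DataFrame(index=cohort.index)
    out["mp_equiv_dose"] = cohort["mp_equiv_dose"].astype(float)
    out["age"] = cohort["age"].astype(float)
    out["female"] = (cohort["sex"] == "female").astype(float)
    out["bmi"] = cohort["bmi"].astype(float)
    out["current_smoker"] = (cohort["smoker"] == "current").astype(float)
    alc = cohort["alcohol"]
    for level, name in (("low", "alcohol_low"), ("moderate", "alcohol_moderate"),
                        ("hazardous", "alcohol_hazardous"), ("ex", "alcohol_ex")):
        out[name] = np.where(alc.isna(), np.nan, (alc == level).astype(float))
    for level, name in (("RA", "ra"), ("SLE", "sle"), ("seroneg_spond", "seroneg")):
        out[name] = (cohort["disease"] == level).astype(float)
    for name in ("diabetes", "ckd3", "five_asa", "sulfasalazine", "mtx_lef",
                 "statin", "allopurinol", "ace_inhibitor", "prior_mild_abnormality"):
        out[name] = cohort[name].astype(float)
    for extra in ("subject_id", "followup_time", "event"):
        if extra in cohort.columns:
            out[extra] = cohort[extra].values
    return out


def _linear_predictor(design: pd.DataFrame, coefficients: Mapping[str, float]) -> np.ndarray:
    beta = np.array([coefficients.get(p, 0.0) for p in PARAMETERS])
    X = design[list(PARAMETERS)].to_numpy(dtype=float)
    return X @ beta


def _solve_intercept(score: np.ndarray, rate: float) -> float:
    """Intercept making mean(sigmoid(a + score)) equal the target rate."""
    if rate <= 0:
        return -np.inf

    def f(a):
        return np.mean(1.0 / (1.0 + np.exp(-(a + score)))) - rate

    return optimize.brentq(f, -30.0, 30.0)


def generate_cohort(
    n: int,
    true_model: TrueModel | None = None,
    marginals: CohortMarginals | None = None,
    seed: int = 0,
    missingness_mechanism: str = "MAR",
) -> pd.DataFrame:
    """Generate a synthetic analysis-ready cohort.

    Returns one row per subject with the predictor fields, ``followup_time``
    in years within (0, 5], the event indicator and the exit ``reason``.
    Bit-reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if missingness_mechanism not in ("MAR", "MCAR"):
        raise ConfigurationError("missingness_mechanism must be 'MAR' or 'MCAR'")
    true_model = true_model if true_model is not None else default_true_model()
    marginals = marginals if marginals is not None else CohortMarginals()
    rng = np.random.default_rng(seed)

    df = _draw_predictors(n, marginals, rng)
    lp = _linear_predictor(to_design_matrix(df), true_model.coefficients)
    hazard = true_model.baseline_hazard_scale * np.exp(lp)

    t_event = rng.exponential(1.0 / hazard)
    clocks = {"admin_end": np.full(n, true_model.admin_horizon)}
    for name, rate in true_model.censoring_rates.items():
        clocks[name] = (rng.exponential(1.0 / rate, size=n) if rate > 0
                        else np.full(n, np.inf))
    all_times = np.column_stack([t_event] + list(clocks.values()))
    labels = np.array(["event"] + list(clocks.keys()))
    winner = np.argmin(all_times, axis=1)
    df["followup_time"] = all_times[np.arange(n), winner]
    df["event"] = (winner == 0).astype(int)
    df["reason"] = labels[winner]
    # exponential draws are continuous: times are strictly positive

    # inject missingness
    z_age = (df["age"] - marginals.age_mean) / marginals.age_sd
    mar_score = (0.35 * z_age + 0.25 * (df["sex"] == "female")
                 + 0.30 * (df["disease"] != "IBD")).to_numpy(dtype=float)
    for fld, rate in true_model.missingness.items():
        if rate <= 0:
            continue
        score = mar_score if missingness_mechanism == "MAR" else np.zeros(n)
        p = 1.0 / (1.0 + np.exp(-(_solve_intercept(score, rate) + score)))
        mask = rng.random(n) < p
        if fld == "alcohol":
            df.loc[mask, "alcohol"] = np.nan
        else:
            df.loc[mask, fld] = np.nan

    df.insert(0, "subject_id", [f"S{i:06d}" for i in range(n)])
    return df


# ---------------------------------------------------------------------------
# calibration of the generator defaults

def expected_event_statistics(
    true_model: TrueModel,
    marginals: CohortMarginals | None = None,
    n_probe: int = 20000,
) -> dict:
    """Expected event fraction, incidence and mean follow-up under the model.

    Uses the closed-form exponential-competing-risks expressions averaged
    over a fixed probe sample of covariate profiles (internal seed, so the
    summary is deterministic and independent of user seeds).
    """
    marginals = marginals if marginals is not None else CohortMarginals()
    rng = np.random.default_rng(987654321)
    df = _draw_predictors(n_probe, marginals, rng)
    lp = _linear_predictor(to_design_matrix(df), true_model.coefficients)
    h = true_model.baseline_hazard_scale * np.exp(lp)
    c = sum(true_model.censoring_rates.values())
    r = h + c
    horizon = true_model.admin_horizon
    p_exit = 1.0 - np.exp(-r * horizon)
    p_event = h / r * p_exit
    e_time = p_exit / r
    return {
        "event_fraction": float(np.mean(p_event)),
        "incidence_per_py": float(np.sum(p_event) / np.sum(e_time)),
        "mean_followup": float(np.mean(e_time)),
    }


@functools.lru_cache(maxsize=4)
def default_true_model(
    target_incidence: float = 0.02513,     # 405 events / 16117 person-years
    target_mean_followup: float = 16117 / 5982,
) -> TrueModel:
    """The default generating model, calibrated to the development cohort.

    The published coefficients act as the truth; the baseline hazard and the
    total censoring-clock rate are solved so the expected crude incidence
    and mean follow-up match the development cohort (which together imply
    the ~6.8% event fraction). Death is held at its negligible observed
    rate and the remaining censoring is split between prescription-gap and
    transfer-out clocks.
    """
    death = 0.00025
    lam0, c_extra = 0.0128, 0.25

    marginals = CohortMarginals()
    rng = np.random.default_rng(987654321)
    lp = _linear_predictor(to_design_matrix(_draw_predictors(20000, marginals, rng)),
                           PUBLISHED_COEFFICIENTS)
    rel = np.exp(lp)

    def stats_for(lam0, c_total):
        h = lam0 * rel
        r = h + c_total
        p_exit = 1.0 - np.exp(-5.0 * r)
        return np.sum(h / r * p_exit) / np.sum(p_exit / r), np.mean(p_exit / r)

    for _ in range(4):
        lam0 = optimize.brentq(
            lambda x: stats_for(x, c_extra + death)[0] - target_incidence, 1e-5, 0.2)
        c_extra = optimize.brentq(
            lambda c: stats_for(lam0, c + death)[1] - target_mean_followup, 1e-4, 2.0)

    return TrueModel(
        baseline_hazard_scale=lam0,
        censoring_rates={"transfer_out": 0.22 * c_extra,
                         "rx_gap": 0.78 * c_extra,
                         "death": death},
    )
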