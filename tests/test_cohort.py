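"""Synthetic cohort generation and the longitudinal ascertainment rules."""

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter

from thiomon.cohort import (AZATHIOPRINE_TO_MP, CohortMarginals,
                            ConfigurationError, LabResult, PrescriptionEvent,
                            TrueModel, ascertain_outcome, classify_abnormal,
                            default_true_model, derive_predictors,
                            expected_event_statistics, generate_cohort,
                            mp_equivalent_dose, to_design_matrix)
from thiomon.risk_model import PARAMETERS

from conftest import random_streams


class TestDoseConversion:
    def test_azathioprine_100_gives_48_1(self):
        assert mp_equivalent_dose("azathioprine", 100) == pytest.approx(48.1)

    def test_mercaptopurine_unchanged(self):
        assert mp_equivalent_dose("mercaptopurine", 50) == 50.0

    def test_conversion_is_linear(self):
        assert mp_equivalent_dose("azathioprine", 50) == pytest.approx(24.05)

    def test_errors(self):
        with pytest.raises(ValueError):
            mp_equivalent_dose("thioguanine", 40)
        with pytest.raises(ValueError):
            mp_equivalent_dose("azathioprine", 0)


class TestClassifyAbnormal:
    @pytest.mark.parametrize("analyte,value,context,expected", [
        ("platelets", 130, "outcome", True),
        ("platelets", 140, "outcome", False),     # strict inequality
        ("platelets", 145, "prior_mild", True),
        ("wbc", 3.4, "outcome", True),
        ("wbc", 3.6, "outcome", False),
        ("wbc", 3.9, "prior_mild", True),
        ("neutrophils", 1.5, "outcome", True),
        ("neutrophils", 1.9, "prior_mild", True),
        ("neutrophils", 1.9, "outcome", False),
        ("alt", 36, "prior_mild", True),
        ("alt", 36, "outcome", False),
        ("alt", 101, "outcome", True),
        ("ast", 35, "prior_mild", False),         # threshold is > 35
    ])
    def test_threshold_table(self, analyte, value, context, expected):
        assert classify_abnormal(analyte, value, context) is expected

    def test_creatinine_rise_rule(self):
        assert classify_abnormal("creatinine", 120, "outcome", previous_value=90)
        assert not classify_abnormal("creatinine", 116, "outcome", previous_value=90)
        assert not classify_abnormal("creatinine", 120, "outcome")  # no prior
        assert not classify_abnormal("creatinine", 300, "prior_mild")

    def test_unknown_analyte_rejected(self):
        with pytest.raises(ValueError):
            classify_abnormal("haemoglobin", 10, "outcome")


def _rx(dates):
    return [PrescriptionEvent("s", d, "azathioprine", 100.0) for d in dates]


class TestAscertainOutcome:
    def test_gap_below_90_days_is_not_an_event(self):
        res = ascertain_outcome(
            _rx([10, 99]), [LabResult("s", 89, "platelets", 100.0)], [],
            followup_start=0, followup_end=188)
        assert res.event == 0 and res.reason == "admin_end"

    def test_gap_with_abnormality_in_window_is_an_event(self):
        labs = [LabResult("s", 159, "alt", 150.0)]  # 59 days after anchor
        res = ascertain_outcome(_rx([10, 80, 100, 220]), labs, [],
                                followup_start=0, followup_end=400)
        assert res.event == 1
        assert res.event_time == pytest.approx(100 / 365.25)

    def test_abnormality_outside_60_day_window_does_not_qualify(self):
        labs = [LabResult("s", 161, "alt", 150.0)]  # 61 days after anchor
        res = ascertain_outcome(_rx([10, 80, 100, 220]), labs, [],
                                followup_start=0, followup_end=400)
        assert res.event == 0 and res.reason == "gap_no_abnormality"

    def test_qualifying_code_counts_like_an_abnormality(self):
        from thiomon.cohort import CodedEvent
        res = ascertain_outcome(_rx([10, 100]), [],
                                [CodedEvent("s", 60, True)],
                                followup_start=0, followup_end=400)
        assert res.event == 1

    def test_empty_prescriptions_rejected(self):
        with pytest.raises(ValueError):
            ascertain_outcome([], [], [], 0, 100)

    def test_agrees_with_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(2024)
        mismatches = 0
        for _ in range(200):
            rx, labs, codes = random_streams(rng)
            start, end = 0, 1000
            got = ascertain_outcome(rx, labs, codes, start, end)
            exp = _oracle(rx, labs, codes, start, end)
            assert (got.event, got.event_time) == exp, "oracle disagreement"
        assert mismatches == 0


def _oracle(rx, labs, codes, start, end):
    """Independent brute-force scan with the thresholds written literally."""
    low = {"wbc": 3.5, "neutrophils": 1.6, "platelets": 140.0}
    high = {"alt": 100.0, "ast": 100.0}
    marks = []
    prev_cr = None
    for r in sorted(labs, key=lambda x: x.date):
        if r.analyte == "creatinine":
            if prev_cr is not None and r.value - prev_cr > 26.0:
                marks.append(r.date)
            prev_cr = r.value
        elif r.analyte in low and r.value < low[r.analyte]:
            marks.append(r.date)
        elif r.analyte in high and r.value > high[r.analyte]:
            marks.append(r.date)
    marks += [c.date for c in codes if c.qualifying]
    dates = [p.date for p in rx if p.date <= end]
    anchors = []
    for i, d in enumerate(dates):
        nxt = dates[i + 1] if i + 1 < len(dates) else None
        if (nxt is not None and nxt - d >= 90) or (nxt is None and end - d >= 90):
            anchors.append(d)
    for a in sorted(anchors):
        if a < start:
            continue
        if any(abs(m - a) <= 60 for m in marks):
            return 1, (a - start) / 365.25
        return 0, (a - start) / 365.25
    return 0, (end - start) / 365.25


class TestDerivePredictors:
    def _obs(self, rows):
        return pd.DataFrame(rows, columns=["date", "field", "value"])

    def _presc(self, rows):
        return pd.DataFrame(rows, columns=["date", "category", "drug",
                                           "dose_mg_day"])

    def test_bmi_outside_two_year_window_is_missing(self):
        obs = self._obs([(1000 - 25 * 30, "bmi", 27.0)])  # ~25 months before
        out = derive_predictors(obs, self._presc([]), [], index_date=1000)
        assert out["bmi"] is None
        obs2 = self._obs([(1000 - 700, "bmi", 27.0)])
        assert derive_predictors(obs2, self._presc([]), [], 1000)["bmi"] == 27.0

    def test_drug_flag_six_month_window(self):
        recent = self._presc([(1000 - 152, "statin", "", 0.0)])   # ~5 months
        old = self._presc([(1000 - 213, "statin", "", 0.0)])      # ~7 months
        assert derive_predictors(self._obs([]), recent, [], 1000)["statin"]
        assert not derive_predictors(self._obs([]), old, [], 1000)["statin"]

    def test_mild_neutropenia_sets_prior_abnormality(self):
        labs = [LabResult("s", 1000 - 120, "neutrophils", 1.9)]
        out = derive_predictors(self._obs([]), self._presc([]), labs, 1000)
        assert out["prior_mild_abnormality"] is True
        labs_ok = [LabResult("s", 1000 - 120, "neutrophils", 2.4)]
        out = derive_predictors(self._obs([]), self._presc([]), labs_ok, 1000)
        assert out["prior_mild_abnormality"] is False

    def test_thiopurine_dose_is_converted(self):
        presc = self._presc([(950, "thiopurine", "azathioprine", 100.0)])
        out = derive_predictors(self._obs([]), presc, [], 1000)
        assert out["mp_equiv_dose"] == pytest.approx(48.1)


class TestGenerateCohort:
    def test_reproducible_for_fixed_seed(self):
        a = generate_cohort(300, seed=9)
        b = generate_cohort(300, seed=9)
        pd.testing.assert_frame_equal(a, b)
        c = generate_cohort(300, seed=10)
        assert not a.equals(c)

    def test_argument_and_configuration_errors(self):
        with pytest.raises(ValueError):
            generate_cohort(0, seed=1)
        with pytest.raises(ConfigurationError):
            CohortMarginals(disease_probs=(0.5, 0.2, 0.2, 0.2))
        with pytest.raises(ConfigurationError):
            TrueModel(baseline_hazard_scale=-1)
        with pytest.raises(ConfigurationError):
            TrueModel(missingness={"age": 0.1})

    def test_followup_within_bounds_and_age_adult(self):
        c = generate_cohort(2000, seed=3)
        assert ((c.followup_time > 0) & (c.followup_time <= 5)).all()
        assert (c.age >= 18).all()
        assert set(c.loc[c.alcohol.notna(), "alcohol"]) <= {
            "none", "low", "moderate", "hazardous", "ex"}

    def test_event_count_within_binomial_99_bounds_at_published_n(self):
        truth = default_true_model()
        c = generate_cohort(5982, truth, seed=7)
        p = expected_event_statistics(truth)["event_fraction"]  # ~0.068
        mu, sd = 5982 * p, np.sqrt(5982 * p * (1 - p))
        assert abs(c.event.sum() - mu) <= 2.58 * sd

    def test_marginals_match_within_three_standard_errors(self):
        m = CohortMarginals()
        c = generate_cohort(5982, seed=21)
        n = len(c)

        def check(frac, p):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(frac - p) <= 3 * se + 1e-9, (frac, p)

        check((c.sex == "female").mean(), m.p_female)
        check((c.smoker == "current").mean(), m.p_smoker)
        check(c.diabetes.mean(), m.p_diabetes)
        check(c.ckd3.mean(), m.p_ckd3)
        check(c.prior_mild_abnormality.mean(), m.p_prior_mild)
        obs_alc = c.alcohol.dropna()
        for lev, p in zip(m.alcohol_levels, m.alcohol_probs):
            # missingness is MAR on age/sex/disease, independent of alcohol
            check((obs_alc == lev).mean(), p)
        for lev, p in zip(m.disease_levels, m.disease_probs):
            check((c.disease == lev).mean(), p)

    def test_missingness_rates_close_to_configured(self):
        truth = default_true_model()
        c = generate_cohort(5982, truth, seed=33)
        for fld, rate in truth.missingness.items():
            se = np.sqrt(rate * (1 - rate) / len(c))
            assert abs(c[fld].isna().mean() - rate) <= 4 * se

    def test_null_model_reduces_to_single_exponential(self):
        lam = 0.15
        truth = TrueModel(coefficients={}, baseline_hazard_scale=lam,
                          censoring_rates={}, missingness={})
        c = generate_cohort(3000, truth, seed=5)
        km = KaplanMeierFitter().fit(c.followup_time, c.event)
        ci = km.confidence_interval_
        for t in (1.0, 2.5, 4.0):
            row = ci[ci.index <= t].iloc[-1]
            assert row.iloc[0] <= np.exp(-lam * t) <= row.iloc[1]

    def test_design_matrix_round_trip_of_coding(self):
        c = generate_cohort(500, seed=6, missingness_mechanism="MCAR")
        d = to_design_matrix(c)
        assert list(PARAMETERS) == [p for p in d.columns if p in PARAMETERS]
        assert ((d["female"] == 1) == (c["sex"] == "female").to_numpy()).all()
        row_alc = d[["alcohol_low", "alcohol_moderate", "alcohol_hazardous",
                     "alcohol_ex"]].sum(axis=1)
        assert (row_alc.dropna() <= 1).all()
        assert d["bmi"].isna().equals(c["bmi"].isna())
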