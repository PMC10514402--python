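"""Monitoring-strategy event tree, iNMB and sensitivity analyses."""

import numpy as np
import pandas as pd
import pytest

from thiomon.health_econ import (DecilePatient, Illness, IllnessParams, PsaSpec,
                                 Strategy, default_params, default_strategies,
                                 expected_outcomes, inmb, run_deterministic,
                                 run_psa, select_decile_patients,
                                 sensitivity_scale_risk)


def _zero_illness_params():
    return IllnessParams(illnesses=(
        Illness("x", {3: 0.0, 6: 0.0, 12: 0.0, 24: 0.0}, 0.0, 1000.0, 0.1),))


class TestStrategies:
    def test_scheduled_appointment_counts(self):
        counts = {s.name: len(s.schedule) for s in default_strategies()}
        assert counts == {"3-monthly": 20, "6-monthly": 10, "annual": 5,
                          "biennial": 2}

    def test_interval_must_divide_testing_period(self):
        with pytest.raises(ValueError):
            Strategy("bad", 7)


class TestSelectDecilePatients:
    def test_uniform_grid_selects_odd_fifth_percentiles(self):
        risks = np.round(np.arange(1, 101) * 0.001, 3)
        pats = select_decile_patients(risks, seed=0)
        assert [p.five_year_risk for p in pats] == pytest.approx(
            [0.005, 0.015, 0.025, 0.035, 0.045, 0.055, 0.065, 0.075, 0.085,
             0.095])
        assert [p.decile for p in pats] == list(range(1, 11))

    def test_identical_risks_give_identical_patients(self):
        pats = select_decile_patients(np.full(200, 0.07), seed=1)
        assert {p.five_year_risk for p in pats} == {0.07}
        det = run_deterministic(pats, default_strategies(), default_params())
        by_strategy = det.groupby("strategy")["inmb_vs_3monthly"].nunique()
        assert (by_strategy == 1).all()

    def test_matches_sort_and_index_oracle_on_skewed_risks(self):
        rng = np.random.default_rng(3)
        risks = rng.beta(1.2, 15, 731)
        pats = select_decile_patients(risks, seed=0)
        srt = np.sort(risks)
        expected = [srt[int(np.ceil(q * 731)) - 1]
                    for q in np.arange(0.05, 1.0, 0.10)]
        assert [p.five_year_risk for p in pats] == pytest.approx(expected)
        assert [p.five_year_risk for p in pats] == sorted(
            p.five_year_risk for p in pats)

    def test_small_samples_interpolate_with_warning(self):
        with pytest.warns(UserWarning, match="interpolat"):
            pats = select_decile_patients(np.linspace(0.01, 0.2, 50), seed=0)
        assert len(pats) == 10


class TestExpectedOutcomes:
    def test_zero_risk_patient_attends_full_schedule(self):
        params = default_params()
        pat = DecilePatient(1, 0.0)
        for s in default_strategies():
            cost, q = expected_outcomes(pat, s, params)
            expected = sum(24.09 * params.discount(t) for t in s.schedule)
            assert cost == pytest.approx(expected, abs=1e-10)
            assert q == 0.0

    def test_zero_illness_probabilities_leave_only_appointment_costs(self):
        params = _zero_illness_params()
        pat = DecilePatient(5, 0.12)
        for s in default_strategies():
            cost, q = expected_outcomes(pat, s, params)
            assert q == 0.0
            # independent enumeration of expected discounted appointments
            lam = -np.log(1 - 0.12) / 5.0
            exp_cost = 0.0
            prev = 0.0
            for t in s.schedule:
                exp_cost += np.exp(-lam * prev) * 24.09 * 1.035 ** -t
                exp_cost += (np.exp(-lam * prev) - np.exp(-lam * t)) \
                    * 24.09 * 1.035 ** -t
                prev = t
            assert cost == pytest.approx(exp_cost, abs=1e-9)

    def test_two_test_toy_matches_hand_enumerated_event_tree(self):
        # undiscounted toy: tests at 2.5y and 5y, one illness
        params = IllnessParams(
            illnesses=(Illness("only", {30: 0.2}, 0.5, 100.0, 0.01),),
            appointment_cost=10.0, discount_rate=0.0)
        strat = Strategy("toy", 30)
        pat = DecilePatient(1, 0.1)
        lam = -np.log(0.9) / 5.0
        s1, s2 = np.exp(-lam * 2.5), np.exp(-lam * 5.0)
        # appointments: test1 always; test2 if no abnormality before 2.5y;
        # plus one cessation appointment whenever an abnormality is detected
        appt = 10.0 * (1 + s1) + 10.0 * ((1 - s1) + (s1 - s2))
        ill = 0.2 * (1 - s2)
        expected_cost = appt + 100.0 * ill
        expected_q = 0.01 * ill
        cost, q = expected_outcomes(pat, strat, params)
        assert cost == pytest.approx(expected_cost, abs=1e-12)
        assert q == pytest.approx(expected_q, abs=1e-12)

    def test_risk_of_one_rejected(self):
        with pytest.raises(ValueError):
            DecilePatient(1, 1.0)

    def test_discounting_reduces_totals(self):
        p0 = IllnessParams(illnesses=default_params().illnesses,
                           discount_rate=0.0)
        p35 = default_params()
        pat = DecilePatient(9, 0.2)
        for s in default_strategies():
            c0, q0 = expected_outcomes(pat, s, p0)
            c35, q35 = expected_outcomes(pat, s, p35)
            assert c35 < c0 and q35 <= q0


class TestINMB:
    def test_reference_against_itself_is_zero(self):
        assert inmb((100.0, 0.5), (100.0, 0.5), 20000) == 0.0

    def test_pure_cost_saving(self):
        assert inmb((50.0, 0.2), (100.0, 0.2), 20000) == pytest.approx(50.0)

    def test_antisymmetry(self):
        a, b = (120.0, 0.31), (95.0, 0.35)
        assert inmb(a, b, 20000) == pytest.approx(-inmb(b, a, 20000))

    def test_linear_in_wtp_with_slope_delta_qaly(self):
        a, b = (120.0, 0.31), (95.0, 0.35)
        i1 = inmb(a, b, 10000)
        i2 = inmb(a, b, 30000)
        assert (i2 - i1) / 20000 == pytest.approx(0.35 - 0.31)


class TestDeterministicAndPsa:
    @pytest.fixture(scope="class")
    def patients(self):
        rng = np.random.default_rng(5)
        return select_decile_patients(rng.beta(1.5, 18, 500), seed=2)

    def test_extended_intervals_dominate_reference_in_base_case(self, patients):
        det = run_deterministic(patients, default_strategies(), default_params())
        extended = det[det.interval_months > 3]
        assert (extended.inmb_vs_3monthly > 0).all()
        assert (det[det.interval_months == 3].inmb_vs_3monthly == 0).all()

    def test_zero_illness_inmb_is_discounted_appointment_saving(self, patients):
        params = _zero_illness_params()
        det = run_deterministic(patients, default_strategies(), params)
        for _, row in det.iterrows():
            pat = next(p for p in patients if p.decile == row.decile)
            strat = next(s for s in default_strategies()
                         if s.name == row.strategy)
            ref = next(s for s in default_strategies() if s.interval == 3)
            c_s, _ = expected_outcomes(pat, strat, params)
            c_r, _ = expected_outcomes(pat, ref, params)
            assert row.inmb_vs_3monthly == pytest.approx(c_r - c_s, abs=1e-9)

    def test_degenerate_psa_reproduces_deterministic_means(self, patients):
        params = default_params()
        det = run_deterministic(patients, default_strategies(), params)
        psa = run_psa(patients, default_strategies(), params, n_draws=5,
                      seed=3, spec=PsaSpec(prob_ess=np.inf, cost_cv=0.0))
        merged = det.merge(psa, on=["decile", "strategy"])
        assert merged.mean_inmb.to_numpy() == pytest.approx(
            merged.inmb_vs_3monthly.to_numpy(), abs=1e-9)

    def test_psa_is_bit_reproducible(self, patients):
        a = run_psa(patients, default_strategies(), default_params(),
                    n_draws=40, seed=9)
        b = run_psa(patients, default_strategies(), default_params(),
                    n_draws=40, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_higher_illness_risk_never_favours_longer_intervals(self, patients):
        base = run_deterministic(patients, default_strategies(),
                                 default_params())
        worse = run_deterministic(patients, default_strategies(),
                                  sensitivity_scale_risk(default_params(), 2.0))
        m = base.merge(worse, on=["decile", "strategy", "interval_months"],
                       suffixes=("_base", "_worse"))
        ext = m[m.interval_months > 3]
        assert (ext.inmb_vs_3monthly_worse <= ext.inmb_vs_3monthly_base
                + 1e-9).all()


class TestSensitivityScaling:
    def test_factor_one_is_identity(self):
        params = default_params()
        assert sensitivity_scale_risk(params, 1.0) == params

    def test_probabilities_clip_at_one_with_warning(self):
        params = IllnessParams(illnesses=(
            Illness("x", {3: 0.5}, 0.5, 10.0, 0.01),))
        with pytest.warns(UserWarning, match="clipped"):
            scaled = sensitivity_scale_risk(params, 3.0)
        assert scaled.illnesses[0].prob_by_interval[3] == 1.0

    def test_triple_risk_reported_crossover_shape(self):
        """Under 3x illness risks the annual-vs-biennial gap narrows or flips
        with increasing decile risk (the qualitative sensitivity pattern)."""
        rng = np.random.default_rng(6)
        pats = select_decile_patients(rng.beta(1.5, 12, 500), seed=2)
        sens = run_deterministic(pats, default_strategies(),
                                 sensitivity_scale_risk(default_params(), 3.0))
        wide = sens.pivot(index="decile", columns="strategy",
                          values="inmb_vs_3monthly")
        gap = (wide["biennial"] - wide["annual"]).to_numpy()
        assert gap[-1] < gap[0]
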