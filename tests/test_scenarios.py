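"""Policy-scenario machinery: eligibility, dosing schedules, deltas."""

import numpy as np
import pandas as pd
import pytest

from flsim.cohort import (PrevalenceResult, SimulationConfig,
                          run_incidence_cohort, run_prevalence)
from flsim.parameters import DAYS_PER_YEAR, BetaParam, DirichletParam
from flsim.pathway import simulate_patient
from flsim.patients import PatientAttributes
from flsim.scenarios import (ScenarioSpec, compare_scenarios,
                             induction_scenario, maintenance_dose_count,
                             maintenance_scenario)
from flsim.survival import TTESpec


def _ww_attrs():
    return PatientAttributes(age=60.0, sex="male", stage_ia=False,
                             flipi="low", management="ww")


class TestScenarioSpec:
    def test_defaults_carry_trial_effects(self):
        s1 = induction_scenario(1.0)
        assert s1.hazard_ratio == 0.35 and s1.hr_ci == (0.22, 0.56)
        s2 = maintenance_scenario(0.5)
        assert s2.hazard_ratio == 0.55 and s2.hr_ci == (0.44, 0.68)

    def test_log_hr_sd_from_ci(self):
        s = induction_scenario(1.0)
        assert s.log_hr_sd == pytest.approx(
            (np.log(0.56) - np.log(0.22)) / 3.92)

    def test_hr_draws_centred_on_point(self):
        rng = np.random.default_rng(2)
        s = maintenance_scenario(1.0)
        draws = np.log([s.draw_hazard_ratio(rng) for _ in range(8000)])
        assert abs(draws.mean() - np.log(0.55)) < 0.01
        assert abs(draws.std() - s.log_hr_sd) < 0.01

    @pytest.mark.parametrize("bad", [
        dict(kind="bogus", hazard_ratio=0.5, hr_ci=(0.3, 0.7), uptake=0.5),
        dict(kind="maintenance", hazard_ratio=0.0, hr_ci=(0.3, 0.7),
             uptake=0.5),
        dict(kind="maintenance", hazard_ratio=0.5, hr_ci=(0.3, 0.7),
             uptake=1.5),
    ])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            ScenarioSpec(**bad)


class TestMaintenanceDoseCount:
    @pytest.mark.parametrize("months,doses", [
        (0, 0), (1.9, 0), (2, 1), (7, 3), (24, 12), (30, 12), (60, 12),
    ])
    def test_schedule_arithmetic(self, months, doses):
        assert maintenance_dose_count(months) == doses

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            maintenance_dose_count(-1)


class TestInduction:
    def test_full_uptake_rescales_time_to_treatment(self, ps):
        # isolate the W&W -> treatment race: competitors numerically removed
        lam = 2.0 / DAYS_PER_YEAR
        ps.transitions["ww_to_treatment"] = TTESpec("exponential", (lam,))
        ps.transitions["ww_to_death"] = TTESpec("exponential", (1e-15,))
        ps.transitions["ww_to_transform"] = TTESpec("exponential", (1e-15,))
        ps.transitions["pretreatment_to_management"] = TTESpec(
            "exponential", (1e6,))
        ps.max_age = 1000.0
        scen = induction_scenario(1.0)
        rng = np.random.default_rng(3)
        srng = np.random.default_rng(4)
        waits = []
        for _ in range(4000):
            traj = simulate_patient(_ww_attrs(), ps, rng, scenario=scen,
                                    scenario_rng=srng)
            start = next(r for r in traj.records if r.event == "start-treatment")
            waits.append(start.time_days)
        mean_years = np.mean(waits) / DAYS_PER_YEAR
        assert mean_years == pytest.approx(1 / (0.35 * 2.0), rel=0.05)

    def test_induction_books_four_weekly_doses(self, ps):
        scen = induction_scenario(1.0)
        rng = np.random.default_rng(5)
        srng = np.random.default_rng(6)
        found = False
        for _ in range(200):
            traj = simulate_patient(_ww_attrs(), ps, rng, scenario=scen,
                                    scenario_rng=srng)
            doses = [r for r in traj.records if r.event == "induction-dose"]
            ww_start = next(r.time_days for r in traj.records
                            if r.event == "start-ww")
            assert len(doses) <= 4
            if len(doses) == 4:
                found = True
                np.testing.assert_allclose(
                    [d.time_days for d in doses],
                    ww_start + np.array([0.0, 7.0, 14.0, 21.0]))
        assert found

    def test_base_case_rituximab_patients_not_reenrolled(self, ps):
        # a base-case induction patient keeps the unmodified transition but
        # still receives the four administrations
        attrs = PatientAttributes(age=60.0, sex="male", stage_ia=False,
                                  flipi="low", management="ww",
                                  ww_rituximab=True)
        rng = np.random.default_rng(7)
        traj = simulate_patient(attrs, ps, rng)
        assert sum(r.event == "induction-dose" for r in traj.records) <= 4


class TestMaintenance:
    def test_doses_match_remission_duration(self, ps):
        scen = maintenance_scenario(1.0)
        rng = np.random.default_rng(8)
        srng = np.random.default_rng(9)
        month = DAYS_PER_YEAR / 12
        checked = 0
        for _ in range(300):
            attrs = PatientAttributes(age=60.0, sex="male", stage_ia=False,
                                      flipi="low", management="chemotherapy")
            traj = simulate_patient(attrs, ps, rng, scenario=scen,
                                    scenario_rng=srng)
            doses = [r for r in traj.records if r.event == "maintenance-dose"]
            rem_months = [(t1 - t0) / month for ph, t0, t1 in traj.segments
                          if ph.endswith("remission")]
            expected = sum(maintenance_dose_count(m) for m in rem_months)
            assert len(doses) == expected
            checked += len(doses)
        assert checked > 0


class TestSeedStreamIsolation:
    def test_zero_uptake_bit_identical_to_base(self, default_ps):
        cfg = SimulationConfig(cohort_size=120, iterations=2, seed=13,
                               horizons_years=(None,))
        base = run_incidence_cohort(default_ps, cfg)
        for scen in (induction_scenario(0.0), maintenance_scenario(0.0)):
            alt = run_incidence_cohort(default_ps, cfg, scenario=scen)
            pd.testing.assert_frame_equal(base.per_iteration,
                                          alt.per_iteration)

    def test_uptake_leaves_non_eligible_patients_untouched(self, ps):
        # everyone is palliative: the induction scenario touches nobody
        from conftest import make_not_treated_ps

        nt = make_not_treated_ps(ps)
        cfg = SimulationConfig(cohort_size=80, iterations=1, seed=17,
                               horizons_years=(None,))
        base = run_incidence_cohort(nt, cfg)
        alt = run_incidence_cohort(nt, cfg, scenario=induction_scenario(1.0))
        pd.testing.assert_frame_equal(base.per_iteration, alt.per_iteration)

    def test_treatment_delay_mechanism(self, default_ps):
        """With dose costs at zero, full-uptake induction cannot increase the
        rate of treatment starts (the delaying mechanism check)."""
        ps = default_ps.copy()
        ps.costs.rituximab_administration = 0.0
        cfg = SimulationConfig(cohort_size=400, iterations=2, seed=19,
                               horizons_years=(10,))
        base = run_incidence_cohort(ps, cfg)
        full = run_incidence_cohort(ps, cfg,
                                    scenario=induction_scenario(1.0))
        # fewer patients progress beyond watch-and-wait within 10 years
        n_ww = lambda s: s.row("ww_only", 10)["n_mean"]  # noqa: E731
        assert n_ww(full) >= n_ww(base)


class TestCompareScenarios:
    @staticmethod
    def _res(costs, sig=("prevalence", 1)):
        arr = np.asarray(costs, dtype=float)
        return PrevalenceResult(annual_costs=arr, annual_costs_fl_only=arr,
                                alive_counts=np.zeros_like(arr),
                                config_signature=sig)

    def test_identical_runs_have_zero_delta(self):
        base = self._res([5.0, 6.0])
        table = compare_scenarios(base, {0.5: self._res([5.0, 6.0])})
        assert table.loc[table["uptake"] == 0.5, "delta_vs_base"].item() == 0.0

    def test_uptake_grid_rows_and_order_stats(self):
        base = self._res([5.0, 6.0])
        grid = {u: self._res([5.0 - u, 6.0 - u]) for u in
                (0.25, 0.5, 0.75, 1.0)}
        table = compare_scenarios(base, grid)
        assert list(table["uptake"]) == [0.0, 0.25, 0.5, 0.75, 1.0]
        assert (table["min_annual_cost"] <= table["mean_annual_cost"]).all()
        assert (table["mean_annual_cost"] <= table["max_annual_cost"]).all()
        assert table["delta_vs_base"].iloc[-1] == pytest.approx(-1.0)

    def test_mismatched_configs_rejected(self):
        with pytest.raises(ValueError):
            compare_scenarios(self._res([1.0]),
                              {1.0: self._res([1.0], sig=("other", 2))})

    def test_prevalence_scenario_end_to_end(self, default_ps):
        ps = default_ps.copy()
        ps.incidence_per_year = 40
        cfg = SimulationConfig(mode="prevalence", iterations=2,
                               burn_in_years=8.0, seed=23)
        base = run_prevalence(ps, cfg)
        scen = run_prevalence(ps, cfg, scenario=maintenance_scenario(1.0))
        table = compare_scenarios(base, {1.0: scen})
        assert len(table) == 2
        assert np.isfinite(table["delta_vs_base"]).all()
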