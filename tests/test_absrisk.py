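"""Baseline calibration and competing-mortality risk accumulation."""

import numpy as np
import pytest

from pancrisk.absrisk import (BaselineHazard, age_specific_incidence,
                              calibrate_baseline, interval_risk, lifetime_risk,
                              risk_percentiles)
from pancrisk.io import LifeTable
from pancrisk.rrmodel import RiskProfile, relative_risk


def flat_table(incidence, mortality, ages=(40, 90), sex="male"):
    n = ages[1] - ages[0] + 1
    return LifeTable(sex=sex, ages=np.arange(ages[0], ages[1] + 1),
                     incidence=np.full(n, incidence),
                     mortality=np.full(n, mortality))


def fine_grid_oracle(h, m, steps_per_year=365):
    """Daily-grid piecewise-constant-hazard integration of disease risk."""
    risk, surv = 0.0, 1.0
    dt = 1.0 / steps_per_year
    for hy, my in zip(h, m):
        for _ in range(steps_per_year):
            tot = (hy + my) * dt
            p_event = 1.0 - np.exp(-tot)
            frac = hy / (hy + my) if hy + my > 0 else 0.0
            risk += surv * frac * p_event
            surv *= np.exp(-tot)
    return risk


class TestCalibration:
    def test_identity_when_all_controls_at_baseline(self, coeffs,
                                                    male_life_table):
        controls = [RiskProfile.baseline()] * 10
        baseline = calibrate_baseline(male_life_table, controls, coeffs)
        assert np.allclose(baseline.rho, male_life_table.incidence)

    def test_division_by_mean_control_rr(self, coeffs):
        table = flat_table(12.0 / 1e5, 0.01)
        # smoking_former (1.22) and a profile pair averaging to a known RR
        controls = [RiskProfile.baseline(), RiskProfile(smoking="current")]
        mean_rr = (1.0 + 2.20) / 2.0
        baseline = calibrate_baseline(table, controls, coeffs)
        assert baseline.mean_control_rr == pytest.approx(mean_rr)
        assert baseline.rho[0] == pytest.approx(12.0 / 1e5 / mean_rr)

    def test_calibration_identity_reproduces_population_rate(
            self, coeffs, paper_scale_sample, male_life_table):
        profiles = [RiskProfile.from_record(r) for r in paper_scale_sample
                    if r.status == "control" and r.sex == "male"]
        baseline = calibrate_baseline(male_life_table, profiles, coeffs)
        rrs = np.array([relative_risk(p, coeffs) for p in profiles])
        # mean over controls of rho(t) * RR_i equals the population rate
        for i in (0, 30, 60, len(baseline.rho) - 1):
            mean_inc = float(np.mean(baseline.rho[i] * rrs))
            assert mean_inc == pytest.approx(male_life_table.incidence[i],
                                             abs=1e-12)

    def test_profiles_with_missing_levels_rejected(self, coeffs,
                                                   male_life_table):
        with pytest.raises(ValueError, match="missing"):
            calibrate_baseline(male_life_table,
                               [RiskProfile(smoking="missing")], coeffs)

    def test_empty_controls_rejected(self, coeffs, male_life_table):
        with pytest.raises(ValueError, match="control"):
            calibrate_baseline(male_life_table, [], coeffs)


class TestAgeSpecificIncidence:
    def test_baseline_profile_returns_rho_exactly(self, coeffs,
                                                  male_life_table):
        baseline = calibrate_baseline(male_life_table,
                                      [RiskProfile.baseline()], coeffs)
        for age in (45, 60, 80):
            assert age_specific_incidence(RiskProfile.baseline(), age,
                                          baseline, coeffs) \
                == baseline.slice(age, age + 1)[0]

    def test_hazard_scales_with_relative_risk(self, coeffs, male_life_table):
        baseline = calibrate_baseline(male_life_table,
                                      [RiskProfile.baseline()], coeffs)
        smoker = RiskProfile(smoking="current")
        assert age_specific_incidence(smoker, 60, baseline, coeffs) \
            == pytest.approx(2.20 * baseline.slice(60, 61)[0])

    def test_age_outside_support_raises(self, coeffs, male_life_table):
        baseline = calibrate_baseline(male_life_table,
                                      [RiskProfile.baseline()], coeffs)
        with pytest.raises(ValueError, match="support"):
            age_specific_incidence(RiskProfile.baseline(), 150, baseline,
                                   coeffs)


class TestIntervalRisk:
    def setup_method(self):
        self.profile = RiskProfile.baseline()

    def _risk(self, coeffs, table, a, b):
        baseline = calibrate_baseline(table, [RiskProfile.baseline()], coeffs)
        return interval_risk(self.profile, a, b, baseline, table, coeffs)

    def test_zero_hazard_gives_zero_risk(self, coeffs):
        table = flat_table(0.0, 0.01)
        assert self._risk(coeffs, table, 50, 70) == 0.0

    def test_no_competing_mortality_closed_form(self, coeffs):
        h = 2e-3
        table = flat_table(h, 0.0)
        n = 20
        assert self._risk(coeffs, table, 50, 70) \
            == pytest.approx(1.0 - np.exp(-n * h), rel=1e-12)

    def test_zero_total_hazard_years_contribute_nothing(self, coeffs):
        table = flat_table(0.0, 0.0)
        assert self._risk(coeffs, table, 40, 90) == 0.0

    def test_matches_fine_grid_oracle(self, coeffs, male_life_table):
        baseline = calibrate_baseline(male_life_table,
                                      [RiskProfile.baseline(),
                                       RiskProfile(smoking="current")], coeffs)
        profile = RiskProfile(smoking="current", bmi_cat="over30", snp_1q32=2)
        value = interval_risk(profile, 50, 85, baseline, male_life_table,
                              coeffs)
        rr = relative_risk(profile, coeffs)
        h = baseline.slice(50, 85) * rr
        _, m = male_life_table.slice(50, 85)
        oracle = fine_grid_oracle(h, m)
        assert value == pytest.approx(oracle, rel=1e-6)

    def test_three_way_decomposition_sums_to_one(self, coeffs):
        rng = np.random.default_rng(3)
        inc = rng.uniform(0, 5e-3, size=51)
        mort = rng.uniform(0, 5e-2, size=51)
        table = LifeTable(sex="male", ages=np.arange(40, 91), incidence=inc,
                          mortality=mort)
        baseline = calibrate_baseline(table, [RiskProfile.baseline()], coeffs)
        disease = interval_risk(self.profile, 40, 90, baseline, table, coeffs)
        # death first: swap the roles of the two hazards on the same grid
        h, m = table.slice(40, 90)
        from pancrisk.absrisk import _accumulate
        death_first = _accumulate(m, h)
        neither = float(np.exp(-np.sum(h + m)))
        assert disease + death_first + neither == pytest.approx(1.0, abs=1e-9)

    def test_interval_splitting_recombines(self, coeffs, male_life_table):
        baseline = calibrate_baseline(male_life_table,
                                      [RiskProfile.baseline()], coeffs)
        profile = RiskProfile(smoking="former", abo="AO")
        whole = interval_risk(profile, 50, 80, baseline, male_life_table,
                              coeffs)
        first = interval_risk(profile, 50, 65, baseline, male_life_table,
                              coeffs)
        second = interval_risk(profile, 65, 80, baseline, male_life_table,
                               coeffs)
        rr = relative_risk(profile, coeffs)
        h, m = male_life_table.slice(50, 65)
        h = baseline.slice(50, 65) * rr
        surv_first = float(np.exp(-np.sum(h + m)))
        assert whole == pytest.approx(first + surv_first * second, rel=1e-12)

    def test_degenerate_interval_rejected(self, coeffs, male_life_table):
        baseline = calibrate_baseline(male_life_table,
                                      [RiskProfile.baseline()], coeffs)
        with pytest.raises(ValueError):
            interval_risk(self.profile, 70, 70, baseline, male_life_table,
                          coeffs)


class TestLifetimeRisk:
    def test_monotone_in_horizon(self, coeffs, male_life_table):
        baseline = calibrate_baseline(male_life_table,
                                      [RiskProfile.baseline()], coeffs)
        risks = [lifetime_risk(RiskProfile.baseline(), 50, baseline,
                               male_life_table, coeffs, horizon_age=h)
                 for h in (60, 70, 80, 85)]
        assert all(a <= b for a, b in zip(risks, risks[1:]))

    def test_horizon_ten_years_out_is_ten_year_risk(self, coeffs,
                                                    female_life_table):
        baseline = calibrate_baseline(female_life_table,
                                      [RiskProfile.baseline()], coeffs)
        profile = RiskProfile(abo="AB")
        assert lifetime_risk(profile, 60, baseline, female_life_table, coeffs,
                             horizon_age=70) \
            == interval_risk(profile, 60, 70, baseline, female_life_table,
                             coeffs)


class TestRiskPercentiles:
    def test_identical_profiles_give_flat_curve(self, coeffs, male_life_table):
        baseline = calibrate_baseline(male_life_table,
                                      [RiskProfile.baseline()], coeffs)
        profiles = [RiskProfile(smoking="former")] * 150
        _, risks = risk_percentiles(profiles, 60, baseline, male_life_table,
                                    coeffs)
        assert np.all(risks == risks[0])

    def test_curve_nondecreasing(self, coeffs, paper_scale_sample,
                                 male_life_table):
        profiles = [RiskProfile.from_record(r) for r in paper_scale_sample
                    if r.sex == "male" and r.status == "control"][:400]
        baseline = calibrate_baseline(male_life_table, profiles, coeffs)
        pct, risks = risk_percentiles(profiles, 60, baseline, male_life_table,
                                      coeffs)
        assert np.all(np.diff(risks) >= 0)
        assert len(pct) == len(profiles)

    def test_empty_population_rejected(self, coeffs, male_life_table):
        baseline = calibrate_baseline(male_life_table,
                                      [RiskProfile.baseline()], coeffs)
        with pytest.raises(ValueError):
            risk_percentiles([], 60, baseline, male_life_table, coeffs)
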