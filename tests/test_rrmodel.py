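"""Covariate coding, ABO derivation, logistic fitting and relative risk."""

import itertools
import math

import numpy as np
import pytest
import statsmodels.api as sm

from pancrisk.io import SubjectRecord
from pancrisk.rrmodel import (CoefficientSet, FitError, RiskProfile, derive_abo,
                              encode, encode_records, fit, load_coefficients,
                              published_coefficients, relative_risk,
                              save_coefficients)

from test_io import make_record


def brute_force_abo(o: int, b: int):
    """Enumerate phase assignments of o O-tag and b B-tag alleles over the
    two haplotype slots; a slot carrying the O tag is an O haplotype, one
    carrying the B tag is B, a bare slot is A, and a slot carrying both
    tags is impossible.  Returns the set of consistent diplotypes in
    canonical (letter-sorted) spelling."""
    results = set()
    for o_slots in itertools.combinations(range(2), o):
        for b_slots in itertools.combinations(range(2), b):
            if set(o_slots) & set(b_slots):
                continue
            labels = ["O" if s in o_slots else "B" if s in b_slots else "A"
                      for s in range(2)]
            results.add("".join(sorted(labels)))
    return results


class TestDeriveABO:
    @pytest.mark.parametrize("o,b,expected", [
        (2, 0, "OO"), (1, 1, "BO"), (1, 0, "AO"),
        (0, 2, "BB"), (0, 1, "AB"), (0, 0, "AA"),
    ])
    def test_matches_phase_enumeration(self, o, b, expected):
        assert derive_abo(o, b) == expected
        consistent = brute_force_abo(o, b)
        assert consistent == {"".join(sorted(expected))}

    @pytest.mark.parametrize("o,b", [(2, 1), (1, 2), (2, 2)])
    def test_more_than_two_haplotypes_is_inconsistent(self, o, b):
        with pytest.raises(ValueError, match="inconsistent"):
            derive_abo(o, b)

    def test_counts_outside_range_rejected(self):
        with pytest.raises(ValueError):
            derive_abo(3, 0)


class TestEncode:
    def test_reference_profile_has_all_nonnuisance_slots_zero(self):
        rec = make_record(age_cat="<50", snp_5p15=0, snp_13q22=0)
        vec = encode(rec, "full")
        nonnuisance = {k: v for k, v in vec.items()
                       if not k.startswith(("age_", "sex_", "study_"))}
        assert all(v == 0 for v in nonnuisance.values())

    def test_former_smoker_indicator_vector(self):
        vec = encode(make_record(smoking="former"), "full")
        assert (vec["smoking_former"], vec["smoking_current"],
                vec["smoking_missing"]) == (1, 0, 0)

    def test_diabetes_effect_is_design_stratified(self):
        cc = encode(make_record(status="case", design="case_control",
                                diabetes="gt3y", diabetes_lag_years=5.0), "full")
        assert cc["diabetes_gt3y_cc"] == 1 and cc["diabetes_gt3y_cohort"] == 0
        coh = encode(make_record(status="case", diabetes="gt3y",
                                 diabetes_lag_years=5.0), "full")
        assert coh["diabetes_gt3y_cohort"] == 1 and coh["diabetes_gt3y_cc"] == 0

    def test_snp_slots_carry_allele_counts(self):
        vec = encode(make_record(snp_13q22=2), "full")
        assert vec["snp_13q22"] == 2.0

    def test_missing_genetics_blocks_genetic_specs_only(self):
        rec = make_record(abo=None, rs505922_alleles=None,
                          rs8176746_alleles=None)
        with pytest.raises(ValueError, match="ABO"):
            encode(rec, "full")
        assert encode(rec, "nongenetic_only")  # complete-case rule not triggered

    def test_abo_derived_from_tag_snps_when_diplotype_absent(self):
        rec = make_record(abo=None, rs505922_alleles=1, rs8176746_alleles=1)
        assert RiskProfile.from_record(rec).abo == "BO"


def two_by_two_records(case_exposed, case_unexposed, control_exposed,
                       control_unexposed):
    records = []
    counts = [("case", "current", case_exposed), ("case", "never", case_unexposed),
              ("control", "current", control_exposed),
              ("control", "never", control_unexposed)]
    i = 0
    for status, smoking, n in counts:
        for _ in range(n):
            records.append(make_record(id=f"r{i}", status=status,
                                       smoking=smoking, age_cat="<50"))
            i += 1
    return records


class TestFit:
    def test_two_by_two_matches_closed_form_log_odds_ratio(self):
        records = two_by_two_records(30, 70, 10, 90)
        fitted = fit(records, "nongenetic_only")
        expected = math.log(30 * 90 / (70 * 10))
        assert fitted.terms["smoking_current"] == pytest.approx(expected,
                                                                abs=1e-8)

    def test_null_association_gives_zero_coefficient(self):
        records = two_by_two_records(20, 80, 20, 80)
        fitted = fit(records, "nongenetic_only")
        assert abs(fitted.terms["smoking_current"]) < 1e-6

    def test_agrees_with_statsmodels_glm(self, small_sample):
        fitted = fit(small_sample, "full")
        X = encode_records(small_sample, "full")
        X = X.loc[:, [c for c in X.columns
                      if c not in fitted.metadata["dropped_terms"]]]
        y = np.array([1.0 if r.status == "case" else 0.0 for r in small_sample])
        ref = sm.GLM(y, X.to_numpy(), family=sm.families.Binomial()).fit()
        ours = np.array([fitted.terms[c] for c in X.columns])
        assert np.allclose(ours, ref.params, atol=1e-6)
        ours_se = np.sqrt(np.diag(fitted.covariance.to_numpy()))
        assert np.allclose(ours_se, ref.bse, rtol=1e-4)

    def test_needs_both_outcomes(self):
        records = [make_record(id=str(i), status="case") for i in range(5)]
        with pytest.raises(FitError, match="case and one control"):
            fit(records, "nongenetic_only")

    def test_separation_is_diagnosed(self):
        records = two_by_two_records(50, 0, 0, 50)
        with pytest.raises(FitError):
            fit(records, "nongenetic_only")

    def test_complete_case_rule_excludes_missing_genotypes(self, small_sample):
        broken = [make_record(id="nog", status="case", abo=None,
                              rs505922_alleles=None, rs8176746_alleles=None)]
        fitted = fit(list(small_sample) + broken, "full")
        assert fitted.metadata["n_genetic_excluded"] == 1
        n = fitted.metadata["n_cases"] + fitted.metadata["n_controls"]
        assert n == len(small_sample)


class TestRelativeRisk:
    def test_reference_profile_is_exactly_one(self, coeffs):
        assert relative_risk(RiskProfile.baseline(), coeffs) == 1.0

    def test_single_factor_equals_published_odds_ratio(self, coeffs):
        rr = relative_risk(RiskProfile(smoking="current"), coeffs)
        assert rr == pytest.approx(2.20)

    def test_multiplicative_across_disjoint_covariates(self, coeffs):
        smoker = RiskProfile(smoking="current")
        obese = RiskProfile(bmi_cat="over30")
        both = RiskProfile(smoking="current", bmi_cat="over30")
        assert relative_risk(both, coeffs) == pytest.approx(
            relative_risk(smoker, coeffs) * relative_risk(obese, coeffs))
        assert relative_risk(both, coeffs) == pytest.approx(2.20 * 1.26)

    @pytest.mark.parametrize("profile", [
        RiskProfile(diabetes="gt3y", design="case_control", abo="AB"),
        RiskProfile(smoking="former", heavy_alcohol="yes", snp_1q32=2,
                    snp_5p15=1, snp_13q22=2),
        RiskProfile(family_history="yes", bmi_cat="under18.5", abo="BB"),
    ])
    def test_log_rr_is_sum_of_selected_terms(self, coeffs, profile):
        from pancrisk.rrmodel import _profile_terms
        expected = sum(coeffs.terms[t] * v
                       for t, v in _profile_terms(profile).items())
        assert math.log(relative_risk(profile, coeffs)) == pytest.approx(expected)

    def test_missing_levels_rejected_in_prediction_mode(self):
        from pancrisk.synth import SimulationConfig, simulate_population
        masked = simulate_population(  # default masking rates, so the
            SimulationConfig(n_cases=700, n_controls=800, seed=11))
        fitted = fit(masked, "full")   # missing-indicator terms are fitted
        profile = RiskProfile(smoking="missing")
        with pytest.raises(ValueError, match="missing"):
            relative_risk(profile, fitted)
        # fitting-parity mode scores the missing-indicator coefficient
        rr = relative_risk(profile, fitted, on_missing="score")
        assert rr == pytest.approx(math.exp(fitted.terms["smoking_missing"]))

    def test_nuisance_terms_are_ignored(self, small_sample):
        fitted = fit(small_sample, "full")
        assert any(t.startswith("age_") for t in fitted.terms)
        assert relative_risk(RiskProfile.baseline(), fitted) == 1.0


class TestCoefficientSet:
    def test_round_trip_serialization(self, tmp_path, small_sample):
        fitted = fit(small_sample, "full")
        path = tmp_path / "coeffs.tsv"
        save_coefficients(fitted, path)
        loaded = load_coefficients(path)
        assert loaded.terms == fitted.terms

    def test_published_set_matches_reported_odds_ratios(self, coeffs):
        ors = coeffs.odds_ratios()
        assert ors["smoking_current"] == pytest.approx(2.20)
        assert ors["snp_1q32"] == pytest.approx(1.29)
        assert ors["abo_BB"] == pytest.approx(1.58)
        assert ors["diabetes_unknown_cohort"] == pytest.approx(2.37)
        assert "intercept" not in coeffs.terms

    def test_indefinite_covariance_rejected(self):
        import pandas as pd
        bad = pd.DataFrame([[1.0, 2.0], [2.0, 1.0]],
                           index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="semidefinite"):
            CoefficientSet(terms={"a": 0.0, "b": 0.0}, covariance=bad)
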