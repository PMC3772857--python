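"""Synthetic case-control data and life tables for the pancreatic-cancer model.

The generator emulates the covariate and genotype structure of the pooled
consortium data the analysis assumes: categorical risk factors drawn per
subject from the control-arm frequencies (separately for the prospective
cohort and retrospective case-control strata), SNP genotypes drawn under
Hardy-Weinberg equilibrium, ABO diplotypes drawn as unordered pairs of
O/A/B haplotypes with tag-SNP allele counts emitted consistently, and
disease status assigned from a logistic model with a configurable true
coefficient set.  Covariates are sampled independently (the source reports
only marginal frequencies); missingness is missing-completely-at-random
with stratum-specific rates, higher in the retrospective stratum.

Because status is Bernoulli with logit = intercept + beta.x and cases and
controls are then subsampled to the requested counts, refitting the
logistic model to the output recovers the true odds ratios (case-control
sampling shifts only the intercept).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .io import LifeTable, SubjectRecord
from .rrmodel import AGE_TERMS, CoefficientSet, published_coefficients

__all__ = ["SimulationConfig", "simulate_population", "simulate_life_table",
           "CONTROL_FREQS", "ALLELE_FREQS", "MISSINGNESS_RATES"]


# ---------------------------------------------------------------------------
# Default frequency structure, transcribed from the pooled consortium
# control arms (counts per stratum; probabilities are computed from these).

_COUNTS = {
    "cohort": {
        "sex": {"male": 732, "female": 713},
        "age_cat": {"<50": 20, "51-60": 161, "61-65": 239, "66-70": 349,
                    "71-75": 349, "76-80": 224, "81+": 103},
        "smoking": {"never": 902, "former": 405, "current": 116},
        "diabetes": {"never": 1309, "gt3y": 67},
        "family_history": {"no": 577, "yes": 20},
        "heavy_alcohol": {"no": 1188, "yes": 82},
        "bmi_cat": {"under18.5": 17, "18.5-25": 585, "25-30": 566,
                    "over30": 267},
    },
    "case_control": {
        "sex": {"male": 1171, "female": 1038},
        "age_cat": {"<50": 219, "51-60": 494, "61-65": 361, "66-70": 366,
                    "71-75": 369, "76-80": 270, "81+": 130},
        "smoking": {"never": 900, "former": 820, "current": 154},
        "diabetes": {"never": 1352, "gt3y": 130},
        "family_history": {"no": 1620, "yes": 66},
        "heavy_alcohol": {"no": 1224, "yes": 136},
        "bmi_cat": {"under18.5": 17, "18.5-25": 695, "25-30": 723,
                    "over30": 287},
    },
}


def _normalise(counts: Mapping[str, float]) -> dict[str, float]:
    total = float(sum(counts.values()))
    return {k: v / total for k, v in counts.items()}


CONTROL_FREQS: dict[str, dict[str, dict[str, float]]] = {
    stratum: {cov: _normalise(c) for cov, c in covs.items()}
    for stratum, covs in _COUNTS.items()
}

# Missing/Not-Available control counts by stratum (denominator: stratum n).
_MISSING_COUNTS = {
    "cohort": {"smoking": 22, "diabetes": 69, "family_history": 848,
               "heavy_alcohol": 175, "bmi_cat": 10},
    "case_control": {"smoking": 315, "diabetes": 727, "family_history": 523,
                     "heavy_alcohol": 849, "bmi_cat": 487},
}
_STRATUM_N = {"cohort": 1445, "case_control": 2209}
MISSINGNESS_RATES = {s: {c: n / _STRATUM_N[s] for c, n in covs.items()}
                     for s, covs in _MISSING_COUNTS.items()}

# O/A/B haplotype frequencies derived by direct allele counting from the
# pooled control diplotype counts (O haplotypes 4766, A 1951, B 585 of
# 7302), and per-SNP risk-allele frequencies counted from the pooled
# control genotype distributions.
ALLELE_FREQS: dict[str, object] = {
    "haplotypes": (4766 / 7302, 1951 / 7302, 585 / 7302),  # (O, A, B)
    "snp_1q32": 5512 / 7306,
    "snp_5p15": 3258 / 7308,
    "snp_13q22": 2692 / 7306,
}

_DESIGN_MIX_COHORT = 1445 / 3654  # cohort fraction among controls

_STUDIES = {"cohort": ("cohort_A", "cohort_B"),
            "case_control": ("cc_A", "cc_B")}

_ABO_FROM_PAIR = {frozenset(p): g for p, g in
                  [(("O", "O"), "OO"), (("A", "O"), "AO"), (("A", "A"), "AA"),
                   (("B", "O"), "BO"), (("B", "B"), "BB"), (("A", "B"), "AB")]}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic case-control draw.

    Defaults reproduce the pooled consortium structure: ~3,349 cases and
    3,654 controls, control-arm covariate frequencies per design stratum,
    Hardy-Weinberg genotypes at the counted control allele frequencies,
    the packaged published coefficient set as the true disease model, and
    stratum-specific MCAR missingness.
    """

    n_cases: int = 3349
    n_controls: int = 3654
    true_coefficients: CoefficientSet = field(default_factory=published_coefficients)
    covariate_freqs: dict = field(default_factory=lambda: {
        s: {c: dict(v) for c, v in covs.items()}
        for s, covs in CONTROL_FREQS.items()})
    allele_freqs: dict = field(default_factory=lambda: dict(ALLELE_FREQS))
    missingness_rates: dict = field(default_factory=lambda: {
        s: dict(v) for s, v in MISSINGNESS_RATES.items()})
    design_mix: float = _DESIGN_MIX_COHORT      # P(design = cohort)
    seed: int = 0
    pool_factor: float = 3.0                    # pool size multiple of n_cases+n_controls
    case_margin: float = 1.25                   # expected cases over requested
    recent_diabetes_rate: float = 0.0           # diabetic cases with lag < 3 y
    non_european_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")
        for stratum, covs in self.covariate_freqs.items():
            for cov, probs in covs.items():
                if abs(sum(probs.values()) - 1.0) > 1e-9:
                    raise ValueError(
                        f"{stratum}/{cov}: probabilities sum to "
                        f"{sum(probs.values())}, not 1")
        hap = self.allele_freqs["haplotypes"]
        if abs(sum(hap) - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")


def no_missingness(config: SimulationConfig) -> SimulationConfig:
    """Copy of ``config`` with every masking rate set to zero."""
    zero = {s: {c: 0.0 for c in covs}
            for s, covs in config.missingness_rates.items()}
    return replace(config, missingness_rates=zero)


def _draw_cat(rng: np.random.Generator, probs: Mapping[str, float],
              size: int) -> np.ndarray:
    levels = list(probs)
    p = np.array([probs[l] for l in levels], dtype=float)
    return np.array(levels, dtype=object)[rng.choice(len(levels), size=size,
                                                     p=p / p.sum())]


def _tune_intercept(lp: np.ndarray, target_cases: float) -> float:
    """Bisection on the intercept so that E[#cases] = target over the pool."""
    lo, hi = -40.0, 40.0

    def expected(c: float) -> float:
        return float(np.sum(1.0 / (1.0 + np.exp(-(c + lp)))))

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expected(mid) < target_cases:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_population(config: SimulationConfig) -> list[SubjectRecord]:
    """Draw a synthetic case-control sample under ``config``.

    A covariate pool of ``pool_factor * (n_cases + n_controls)`` subjects is
    generated; the logistic intercept is tuned by bisection so the expected
    case yield is ``case_margin * n_cases`` (the source model states no
    baseline prevalence); status is drawn Bernoulli per subject and the
    requested numbers of cases and controls are then taken.  Output is
    reproducible given the seed.
    """
    rng = np.random.default_rng(config.seed)
    n_pool = int(math.ceil(config.pool_factor * (config.n_cases + config.n_controls)))

    design = np.where(rng.random(n_pool) < config.design_mix,
                      "cohort", "case_control").astype(object)
    study = np.empty(n_pool, dtype=object)
    covs: dict[str, np.ndarray] = {}
    for cov in ("sex", "age_cat", "smoking", "diabetes", "family_history",
                "heavy_alcohol", "bmi_cat"):
        covs[cov] = np.empty(n_pool, dtype=object)
    for stratum in ("cohort", "case_control"):
        idx = np.flatnonzero(design == stratum)
        study[idx] = _draw_cat(rng, {s: 0.5 for s in _STUDIES[stratum]}, idx.size)
        for cov in covs:
            covs[cov][idx] = _draw_cat(
                rng, config.covariate_freqs[stratum][cov], idx.size)

    # ABO haplotype pairs and tag-SNP counts, consistent by construction
    hap_p = np.asarray(config.allele_freqs["haplotypes"], dtype=float)
    hap_labels = np.array(["O", "A", "B"], dtype=object)
    h1 = hap_labels[rng.choice(3, size=n_pool, p=hap_p / hap_p.sum())]
    h2 = hap_labels[rng.choice(3, size=n_pool, p=hap_p / hap_p.sum())]
    abo = np.array([_ABO_FROM_PAIR[frozenset((a, b)) if a != b
                                   else frozenset((a,))]
                    for a, b in zip(h1, h2)], dtype=object)
    o_count = (h1 == "O").astype(int) + (h2 == "O").astype(int)
    b_count = (h1 == "B").astype(int) + (h2 == "B").astype(int)

    snps: dict[str, np.ndarray] = {}
    for snp in ("snp_1q32", "snp_5p15", "snp_13q22"):
        f = float(config.allele_freqs[snp])
        snps[snp] = rng.binomial(2, f, size=n_pool)

    # linear predictor from the true coefficients (before missingness).
    # Vectorized level-to-coefficient maps; agrees with summing the encoded
    # profile terms subject by subject (checked in the test suite).
    terms = config.true_coefficients.terms
    g = terms.get
    lp = np.zeros(n_pool)

    def _map(values: np.ndarray, table: Mapping[str, float]) -> np.ndarray:
        return np.array([table[v] for v in values])

    lp += _map(covs["smoking"], {"never": 0.0, "former": g("smoking_former", 0.0),
                                 "current": g("smoking_current", 0.0),
                                 "missing": g("smoking_missing", 0.0)})
    dia_key = np.char.add(np.char.add(covs["diabetes"].astype(str), "|"),
                          design.astype(str))
    dia_map = {"never|cohort": 0.0, "never|case_control": 0.0,
               "gt3y|cohort": g("diabetes_gt3y_cohort", 0.0),
               "unknown|cohort": g("diabetes_unknown_cohort", 0.0),
               "gt3y|case_control": g("diabetes_gt3y_cc", 0.0),
               "unknown|case_control": g("diabetes_unknown_cc", 0.0)}
    lp += _map(dia_key, dia_map)
    lp += _map(covs["family_history"], {"no": 0.0, "yes": g("famhx_yes", 0.0),
                                        "missing": g("famhx_missing", 0.0)})
    lp += _map(covs["heavy_alcohol"], {"no": 0.0, "yes": g("alcohol_yes", 0.0),
                                       "missing": g("alcohol_missing", 0.0)})
    lp += _map(covs["bmi_cat"], {"18.5-25": 0.0,
                                 "under18.5": g("bmi_under18_5", 0.0),
                                 "25-30": g("bmi_25_30", 0.0),
                                 "over30": g("bmi_over30", 0.0),
                                 "missing": g("bmi_missing", 0.0)})
    lp += _map(abo, {"OO": 0.0, "AO": g("abo_AO", 0.0), "AA": g("abo_AA", 0.0),
                     "BO": g("abo_BO", 0.0), "BB": g("abo_BB", 0.0),
                     "AB": g("abo_AB", 0.0)})
    for snp in ("snp_1q32", "snp_5p15", "snp_13q22"):
        lp += g(snp, 0.0) * snps[snp]
    # nuisance truths, when the coefficient set carries them
    lp += _map(covs["age_cat"],
               {level: g(term, 0.0) for level, term in AGE_TERMS.items()}
               | {"<50": 0.0})
    lp += np.where(covs["sex"] == "female", g("sex_female", 0.0), 0.0)
    lp += np.array([g(f"study_{s}", 0.0) for s in study])

    intercept = _tune_intercept(lp, config.case_margin * config.n_cases)
    p = 1.0 / (1.0 + np.exp(-(intercept + lp)))
    status = rng.random(n_pool) < p

    case_idx = np.flatnonzero(status)
    control_idx = np.flatnonzero(~status)
    if case_idx.size < config.n_cases or control_idx.size < config.n_controls:
        raise RuntimeError(
            f"pool of {n_pool} yielded {case_idx.size} cases / "
            f"{control_idx.size} controls; need {config.n_cases}/"
            f"{config.n_controls} -- increase pool_factor")
    chosen = np.concatenate([case_idx[:config.n_cases],
                             control_idx[:config.n_controls]])

    # MCAR masking, applied after status assignment
    for stratum in ("cohort", "case_control"):
        for cov, rate in config.missingness_rates[stratum].items():
            if rate <= 0:
                continue
            hit = (design == stratum) & (rng.random(n_pool) < rate)
            level = "unknown" if cov == "diabetes" else "missing"
            covs[cov][hit] = level

    non_euro = rng.random(n_pool) < config.non_european_rate
    lag_u = rng.random(n_pool)          # drawn unconditionally for reproducibility
    recent = rng.random(n_pool) < config.recent_diabetes_rate

    records = []
    for k, i in enumerate(chosen):
        is_case = bool(status[i])
        lag = None
        if is_case and covs["diabetes"][i] == "gt3y":
            if recent[i]:
                lag = round(3.0 * lag_u[i], 1)
            else:
                lag = round(3.0 + 17.0 * lag_u[i], 1)
        records.append(SubjectRecord(
            id=f"S{k:06d}", status="case" if is_case else "control",
            design=str(design[i]), study=str(study[i]), sex=str(covs["sex"][i]),
            age_cat=str(covs["age_cat"][i]), smoking=str(covs["smoking"][i]),
            diabetes=str(covs["diabetes"][i]), diabetes_lag_years=lag,
            family_history=str(covs["family_history"][i]),
            heavy_alcohol=str(covs["heavy_alcohol"][i]),
            bmi_cat=str(covs["bmi_cat"][i]), abo=str(abo[i]),
            rs505922_alleles=int(o_count[i]), rs8176746_alleles=int(b_count[i]),
            snp_1q32=int(snps["snp_1q32"][i]), snp_5p15=int(snps["snp_5p15"][i]),
            snp_13q22=int(snps["snp_13q22"][i]),
            ancestry="non-european" if non_euro[i] else "european"))
    return records


# ---------------------------------------------------------------------------
# Synthetic life tables

# Default Gompertz anchors per sex, chosen so that integrating the raw
# incidence over ages 0-85 under competing mortality gives a lifetime risk
# near the published population anchors (~1.5% for men, slightly lower for
# women) with registry-like age shapes.
_LIFE_DEFAULTS = {
    "male": {"incidence_at_60": 27.8e-5, "incidence_slope": 0.070,
             "mortality_at_60": 0.0095, "mortality_slope": 0.085},
    "female": {"incidence_at_60": 21.6e-5, "incidence_slope": 0.072,
               "mortality_at_60": 0.0060, "mortality_slope": 0.092},
}


def simulate_life_table(sex: str, *, incidence_at_60: float | None = None,
                        incidence_slope: float | None = None,
                        mortality_at_60: float | None = None,
                        mortality_slope: float | None = None,
                        onset_age: int = 30, max_age: int = 99) -> LifeTable:
    """Gompertz-shaped synthetic life table standing in for registry rates.

    Incidence is ``incidence_at_60 * exp(slope * (age - 60))`` above the
    onset age and exactly zero below it; all-cause mortality is a Gompertz
    hazard, monotone nondecreasing in age.  A slope of zero gives constant
    incidence at the baseline value.  Parameters producing a hazard >= 1
    anywhere on the grid raise a value error.
    """
    defaults = _LIFE_DEFAULTS[sex]
    a = defaults["incidence_at_60"] if incidence_at_60 is None else incidence_at_60
    b = defaults["incidence_slope"] if incidence_slope is None else incidence_slope
    m0 = defaults["mortality_at_60"] if mortality_at_60 is None else mortality_at_60
    g = defaults["mortality_slope"] if mortality_slope is None else mortality_slope
    if a < 0 or m0 < 0 or g < 0:
        raise ValueError("rates and the mortality slope must be nonnegative")
    ages = np.arange(0, max_age + 1)
    inc = np.where(ages >= onset_age, a * np.exp(b * (ages - 60.0)), 0.0)
    mort = m0 * np.exp(g * (ages - 60.0))
    if np.any(inc >= 1) or np.any(mort >= 1):
        raise ValueError("parameters produce a hazard >= 1 on the age grid")
    return LifeTable(sex=sex, ages=ages, incidence=inc, mortality=mort)
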