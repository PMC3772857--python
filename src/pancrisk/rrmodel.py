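"""Relative-risk model for pancreatic cancer case-control data.

The model is a multivariable logistic regression of case-control status on
categorical risk factors (smoking, diabetes history, family history of
pancreatic cancer, heavy alcohol use, BMI category), ABO blood-group
diplotype, and per-allele counts at three GWAS risk loci (1q32, 5p15,
13q22), adjusted for sex, age category and study.  Missing covariate data
are handled by the missing-indicator method: "missing" is its own level
with its own coefficient.  The diabetes effect is stratified by study
design (prospective nested case-control vs. retrospective case-control).

The relative risk RR(X) of a risk profile X is exp of the sum of the
profile's non-nuisance log-odds terms; the reference profile (never smoker,
no diabetes, no family history, <=3 drinks/day, BMI 18.5-25, OO genotype,
zero risk alleles) has RR = 1 by construction.  Nuisance terms (age, sex,
study) are estimated during fitting but excluded from RR(X): absolute-risk
calculations anchor age and sex to registry incidence rates instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CoefficientSet",
    "RiskProfile",
    "derive_abo",
    "encode",
    "encode_records",
    "fit",
    "relative_risk",
    "load_coefficients",
    "save_coefficients",
    "published_coefficients",
    "FitError",
    "NONGENETIC_TERMS",
    "GENETIC_TERMS",
]


class FitError(RuntimeError):
    """Raised when the logistic fit cannot be completed (separation,
    rank deficiency or non-convergence)."""


# ---------------------------------------------------------------------------
# Term catalogue.  Reference levels carry an implicit coefficient of zero and
# never appear as terms.

SMOKING_TERMS = {"former": "smoking_former", "current": "smoking_current",
                 "missing": "smoking_missing"}
DIABETES_TERMS = {
    ("gt3y", "cohort"): "diabetes_gt3y_cohort",
    ("unknown", "cohort"): "diabetes_unknown_cohort",
    ("gt3y", "case_control"): "diabetes_gt3y_cc",
    ("unknown", "case_control"): "diabetes_unknown_cc",
}
FAMHX_TERMS = {"yes": "famhx_yes", "missing": "famhx_missing"}
ALCOHOL_TERMS = {"yes": "alcohol_yes", "missing": "alcohol_missing"}
BMI_TERMS = {"under18.5": "bmi_under18_5", "25-30": "bmi_25_30",
             "over30": "bmi_over30", "missing": "bmi_missing"}
ABO_TERMS = {"AO": "abo_AO", "AA": "abo_AA", "BO": "abo_BO",
             "BB": "abo_BB", "AB": "abo_AB"}
SNP_TERMS = ("snp_1q32", "snp_5p15", "snp_13q22")

NONGENETIC_TERMS: tuple[str, ...] = (
    tuple(SMOKING_TERMS.values())
    + tuple(DIABETES_TERMS.values())
    + tuple(FAMHX_TERMS.values())
    + tuple(ALCOHOL_TERMS.values())
    + tuple(BMI_TERMS.values())
)
GENETIC_TERMS: tuple[str, ...] = tuple(ABO_TERMS.values()) + SNP_TERMS

AGE_TERMS = {"51-60": "age_51_60", "61-65": "age_61_65", "66-70": "age_66_70",
             "71-75": "age_71_75", "76-80": "age_76_80", "81+": "age_81plus"}

NUISANCE_PREFIXES = ("age_", "sex_", "study_", "intercept")

ModelSpec = Literal["full", "nongenetic_only", "genetic_only"]


def _spec_terms(model_spec: ModelSpec) -> tuple[str, ...]:
    if model_spec == "full":
        return NONGENETIC_TERMS + GENETIC_TERMS
    if model_spec == "nongenetic_only":
        return NONGENETIC_TERMS
    if model_spec == "genetic_only":
        return GENETIC_TERMS
    raise ValueError(f"unknown model spec {model_spec!r}")


@dataclass
class CoefficientSet:
    """Named log-odds terms of a fitted or transcribed relative-risk model.

    ``terms`` maps term names (see the module catalogue) to log-odds values.
    Nuisance terms (``age_*``, ``sex_female``, ``study_*``, ``intercept``)
    may be present after fitting; :func:`relative_risk` ignores them.
    ``covariance``, when present, is the observed-information covariance
    matrix of the fitted terms, indexed by term name.
    """

    terms: dict[str, float]
    covariance: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    def odds_ratios(self) -> dict[str, float]:
        """exp(term) for every non-nuisance term."""
        return {t: math.exp(v) for t, v in self.terms.items()
                if not t.startswith(NUISANCE_PREFIXES)}

    def __post_init__(self) -> None:
        if self.covariance is not None:
            cov = np.asarray(self.covariance, dtype=float)
            eig = np.linalg.eigvalsh((cov + cov.T) / 2.0)
            if eig.min() < -1e-8 * max(1.0, eig.max()):
                raise ValueError("covariance matrix is not positive semidefinite")


@dataclass(frozen=True)
class RiskProfile:
    """The non-nuisance covariates a relative risk is computed from."""

    smoking: str = "never"
    diabetes: str = "never"
    design: str = "cohort"          # selects the diabetes stratum term
    family_history: str = "no"
    heavy_alcohol: str = "no"
    bmi_cat: str = "18.5-25"
    abo: str = "OO"
    snp_1q32: int = 0
    snp_5p15: int = 0
    snp_13q22: int = 0

    @classmethod
    def baseline(cls) -> "RiskProfile":
        return cls()

    @classmethod
    def from_record(cls, record) -> "RiskProfile":
        abo = record.abo
        if abo is None and record.rs505922_alleles is not None \
                and record.rs8176746_alleles is not None:
            abo = derive_abo(record.rs505922_alleles, record.rs8176746_alleles)
        if abo is None:
            raise ValueError(f"record {record.id}: ABO diplotype unavailable")
        if record.snp_1q32 is None or record.snp_5p15 is None \
                or record.snp_13q22 is None:
            raise ValueError(f"record {record.id}: SNP allele counts unavailable")
        return cls(smoking=record.smoking, diabetes=record.diabetes,
                   design=record.design, family_history=record.family_history,
                   heavy_alcohol=record.heavy_alcohol, bmi_cat=record.bmi_cat,
                   abo=abo, snp_1q32=record.snp_1q32,
                   snp_5p15=record.snp_5p15, snp_13q22=record.snp_13q22)

    def has_missing(self) -> bool:
        return "missing" in (self.smoking, self.family_history,
                             self.heavy_alcohol, self.bmi_cat) \
            or self.diabetes == "unknown"


# ---------------------------------------------------------------------------
# ABO diplotype from tag SNPs

_ABO_BY_COUNTS = {(2, 0): "OO", (1, 1): "BO", (1, 0): "AO",
                  (0, 2): "BB", (0, 1): "AB", (0, 0): "AA"}


def derive_abo(rs505922_alleles: int, rs8176746_alleles: int) -> str:
    """ABO diplotype from the counts of the O-tagging (rs505922) and
    B-tagging (rs8176746) alleles.

    The two tag SNPs are perfectly correlated with the O and B haplotypes,
    so a person's haplotype pair contains ``o`` O-haplotypes, ``b``
    B-haplotypes and ``2 - o - b`` A-haplotypes.  A B-tag allele cannot
    ride on an O haplotype, so ``o + b > 2`` is inconsistent.
    """
    o, b = int(rs505922_alleles), int(rs8176746_alleles)
    if not (0 <= o <= 2 and 0 <= b <= 2):
        raise ValueError(f"allele counts must be in 0..2, got ({o}, {b})")
    if o + b > 2:
        raise ValueError(
            f"inconsistent tag-SNP counts ({o}, {b}): more than two haplotypes implied")
    return _ABO_BY_COUNTS[(o, b)]


# ---------------------------------------------------------------------------
# Encoding

def _profile_terms(profile: RiskProfile, model_spec: ModelSpec = "full"
                   ) -> dict[str, float]:
    """Non-nuisance term values selected by a profile (indicator/count slots)."""
    out: dict[str, float] = {}
    include_ng = model_spec in ("full", "nongenetic_only")
    include_g = model_spec in ("full", "genetic_only")
    if include_ng:
        if profile.smoking != "never":
            out[SMOKING_TERMS[profile.smoking]] = 1.0
        if profile.diabetes != "never":
            out[DIABETES_TERMS[(profile.diabetes, profile.design)]] = 1.0
        if profile.family_history != "no":
            out[FAMHX_TERMS[profile.family_history]] = 1.0
        if profile.heavy_alcohol != "no":
            out[ALCOHOL_TERMS[profile.heavy_alcohol]] = 1.0
        if profile.bmi_cat != "18.5-25":
            out[BMI_TERMS[profile.bmi_cat]] = 1.0
    if include_g:
        if profile.abo != "OO":
            out[ABO_TERMS[profile.abo]] = 1.0
        for term, count in zip(SNP_TERMS, (profile.snp_1q32, profile.snp_5p15,
                                           profile.snp_13q22)):
            if int(count) not in (0, 1, 2):
                raise ValueError(f"{term}: allele count {count} outside 0..2")
            if count:
                out[term] = float(count)
    return out


def encode(record, model_spec: ModelSpec = "full",
           studies: Sequence[str] | None = None) -> dict[str, float]:
    """Term-indexed indicator/count vector for one subject record.

    Emits one slot per catalogue term of ``model_spec`` plus nuisance slots
    for age category and sex (study indicators are added when ``studies``
    lists the study levels; the first level is the reference).  Records
    missing any genetic marker cannot be encoded under a spec that includes
    genetic terms (complete-case rule).
    """
    if model_spec in ("full", "genetic_only"):
        profile = RiskProfile.from_record(record)  # raises if genetics absent
    else:
        profile = RiskProfile(
            smoking=record.smoking, diabetes=record.diabetes,
            design=record.design, family_history=record.family_history,
            heavy_alcohol=record.heavy_alcohol, bmi_cat=record.bmi_cat)
    vec = dict.fromkeys(_spec_terms(model_spec), 0.0)
    vec.update(_profile_terms(profile, model_spec))
    for level, term in AGE_TERMS.items():
        vec[term] = 1.0 if record.age_cat == level else 0.0
    vec["sex_female"] = 1.0 if record.sex == "female" else 0.0
    if studies is not None:
        for s in studies[1:]:
            vec[f"study_{s}"] = 1.0 if record.study == s else 0.0
    return vec


def encode_records(records: Sequence, model_spec: ModelSpec = "full"
                   ) -> pd.DataFrame:
    """Design-matrix DataFrame (one row per record) with an intercept column."""
    studies = sorted({r.study for r in records})
    rows = [encode(r, model_spec, studies=studies) for r in records]
    X = pd.DataFrame(rows, index=[r.id for r in records], dtype=float)
    X.insert(0, "intercept", 1.0)
    return X


# ---------------------------------------------------------------------------
# Fitting: IRLS (Newton-Raphson with step-halving on the log-likelihood)

_MAX_ITER = 100
_SCORE_TOL = 1e-8
_LL_RELTOL = 1e-10


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit(records: Sequence, model_spec: ModelSpec = "full") -> CoefficientSet:
    """Maximum-likelihood logistic fit of case-control status on the model terms.

    Subjects missing any genetic marker are excluded when the spec includes
    genetic terms (complete-case rule for genotypes); missing non-genetic
    covariates stay in via their missing-indicator level.  All-zero columns
    (levels unobserved in the data) are dropped and listed in the metadata.
    """
    genetic = model_spec in ("full", "genetic_only")
    used, n_genetic_excluded = [], 0
    for r in records:
        if genetic:
            try:
                RiskProfile.from_record(r)
            except ValueError:
                n_genetic_excluded += 1
                continue
        used.append(r)
    y = np.array([1.0 if r.status == "case" else 0.0 for r in used])
    if y.sum() == 0 or y.sum() == len(y):
        raise FitError("need at least one case and one control")

    X_df = encode_records(used, model_spec)
    nonzero = (X_df != 0).any(axis=0)
    dropped = list(X_df.columns[~nonzero])
    X_df = X_df.loc[:, nonzero]
    names = list(X_df.columns)
    X = X_df.to_numpy()

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name one offending column: the one whose removal restores full rank
        for j, name in enumerate(names):
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank:
                raise FitError(f"design matrix is rank deficient (term {name!r})")
        raise FitError("design matrix is rank deficient")

    beta = np.zeros(X.shape[1])
    ll = _loglik(y, X @ beta)
    trace = [ll]
    for _ in range(_MAX_ITER):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        score = X.T @ (y - p)
        if np.max(np.abs(score)) < _SCORE_TOL:
            break
        w = p * (1.0 - p)
        info = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"information matrix singular: {exc}") from exc
        # step-halving to guarantee likelihood ascent
        factor = 1.0
        for _half in range(30):
            ll_new = _loglik(y, X @ (beta + factor * step))
            if ll_new >= ll:
                break
            factor /= 2.0
        beta = beta + factor * step
        if np.max(np.abs(beta)) > 30.0:
            j = int(np.argmax(np.abs(beta)))
            raise FitError(f"apparent separation on term {names[j]!r} "
                           f"(|beta| > 30)")
        ll_prev, ll = ll, ll_new
        trace.append(ll)
        if abs(ll - ll_prev) < _LL_RELTOL * (abs(ll_prev) + 1e-300):
            break
    else:
        raise FitError(f"no convergence after {_MAX_ITER} iterations; "
                       f"log-likelihood trace: {trace}")

    p = 1.0 / (1.0 + np.exp(-(X @ beta)))
    w = p * (1.0 - p)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    return CoefficientSet(
        terms=dict(zip(names, beta.tolist())),
        covariance=pd.DataFrame(cov, index=names, columns=names),
        metadata={"model_spec": model_spec, "n_cases": int(y.sum()),
                  "n_controls": int(len(y) - y.sum()),
                  "n_genetic_excluded": n_genetic_excluded,
                  "dropped_terms": dropped, "loglik": ll,
                  "n_iter": len(trace) - 1})


# ---------------------------------------------------------------------------
# Relative risk

def relative_risk(profile: RiskProfile, coeffs: CoefficientSet,
                  model_spec: ModelSpec = "full",
                  on_missing: Literal["raise", "score"] = "raise") -> float:
    """RR(X) = exp(sum of the non-nuisance log-odds terms selected by X).

    Nuisance terms (age, sex, study, intercept) are never included: the
    relative risk is anchored to the reference profile, which maps to
    exactly 1.0.  By default a profile containing a 'missing' level is
    rejected (prediction mode); ``on_missing='score'`` scores it with the
    fitted missing-indicator coefficients instead (fitting parity).
    """
    if profile.has_missing() and on_missing == "raise":
        raise ValueError("profile contains a 'missing' level; pass "
                         "on_missing='score' to use missing-indicator terms")
    total = 0.0
    for term, value in _profile_terms(profile, model_spec).items():
        if term not in coeffs.terms:
            raise KeyError(f"coefficient set has no term {term!r} "
                           f"required by the profile")
        total += coeffs.terms[term] * value
    return math.exp(total)


# ---------------------------------------------------------------------------
# Serialization: flat key-value text (term<TAB>log_odds), '#' comments

def save_coefficients(coeffs: CoefficientSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in coeffs.metadata.items():
            fh.write(f"# {key}: {value}\n")
        for term, value in coeffs.terms.items():
            fh.write(f"{term}\t{value!r}\n")


def load_coefficients(path) -> CoefficientSet:
    terms: dict[str, float] = {}
    meta: dict = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    k, v = line[1:].split(":", 1)
                    meta[k.strip()] = v.strip()
                continue
            term, value = line.split("\t")
            terms[term] = float(value)
    return CoefficientSet(terms=terms, metadata=meta)


def published_coefficients() -> CoefficientSet:
    """The packaged final-model coefficient set (log odds ratios transcribed
    from the published multivariable model).  Supports RR(X) only: no
    nuisance (age/sex/study) or missing-indicator terms were published."""
    from importlib.resources import files
    path = files("pancrisk.data").joinpath("published_model.tsv")
    odds = {}
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            odds[parts[0]] = float(parts[1])
    return CoefficientSet(terms={t: math.log(v) for t, v in odds.items()},
                          metadata={"source": "published multivariable final model"})
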