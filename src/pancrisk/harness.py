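"""Reusable simulation studies built from the package's own pieces.

These drive the end-to-end checks: simulate a case-control sample at the
pooled-consortium scale with the packaged published coefficients as the
true disease model, refit the relative-risk model, and summarise how well
the odds ratios are recovered; score the simulated subjects to measure
model discrimination; and push control profiles through the absolute-risk
pipeline to characterise the lifetime-risk distribution.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .absrisk import calibrate_baseline, lifetime_risk
from .evaluate import auroc
from .rrmodel import CoefficientSet, RiskProfile, fit, published_coefficients, \
    relative_risk
from .synth import SimulationConfig, no_missingness, simulate_life_table, \
    simulate_population

__all__ = ["replicate_seeds", "parameter_recovery", "discrimination_study",
           "lifetime_risk_study"]


def replicate_seeds(base_seed: int, n: int) -> list[int]:
    """n reproducible 31-bit child seeds derived from one base seed."""
    state = np.random.SeedSequence(base_seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def parameter_recovery(n_replicates: int = 20, base_seed: int = 1,
                       n_cases: int = 3349, n_controls: int = 3654,
                       true_coefficients: CoefficientSet | None = None,
                       missingness: bool = False) -> pd.DataFrame:
    """Simulate-and-refit study: one row of recovered odds ratios per replicate.

    Each replicate draws a fresh case-control sample under the true
    coefficient set (the packaged published model by default, no masking)
    and refits the full model; the returned frame holds exp(beta) for every
    fitted non-nuisance term, one column per term.
    """
    truth = true_coefficients or published_coefficients()
    rows = []
    for seed in replicate_seeds(base_seed, n_replicates):
        config = SimulationConfig(n_cases=n_cases, n_controls=n_controls,
                                  true_coefficients=truth, seed=seed)
        if not missingness:
            config = no_missingness(config)
        records = simulate_population(config)
        fitted = fit(records, "full")
        rows.append(fitted.odds_ratios())
    return pd.DataFrame(rows)


def discrimination_study(seed: int = 0, model_spec: str = "full",
                         coeffs: CoefficientSet | None = None,
                         config: SimulationConfig | None = None):
    """AUROC of a coefficient set's risk score on a fresh simulated sample.

    Subjects are scored with the log relative risk (monotone in RR, so the
    AUROC is the same either way); scoring uses missing-indicator parity so
    masked records stay in, mirroring a fit-set evaluation.
    """
    scorer = coeffs or published_coefficients()
    cfg = config or no_missingness(SimulationConfig(seed=seed))
    records = simulate_population(cfg)
    case_scores, control_scores = [], []
    for r in records:
        rr = relative_risk(RiskProfile.from_record(r), scorer,
                           model_spec=model_spec, on_missing="score")
        (case_scores if r.status == "case" else control_scores).append(
            math.log(rr))
    return auroc(case_scores, control_scores)


def lifetime_risk_study(seed: int = 0, sex: str = "male", start_age: int = 50,
                        horizon_age: int = 85,
                        coeffs: CoefficientSet | None = None) -> pd.Series:
    """Lifetime risks of the simulated complete-data controls of one sex.

    Calibrates the synthetic life table to the control relative risks and
    returns one absolute risk per control, as a Series.
    """
    scorer = coeffs or published_coefficients()
    records = simulate_population(no_missingness(SimulationConfig(seed=seed)))
    profiles = [RiskProfile.from_record(r) for r in records
                if r.status == "control" and r.sex == sex]
    table = simulate_life_table(sex)
    baseline = calibrate_baseline(table, profiles, scorer)
    risks = [lifetime_risk(p, start_age, baseline, table, scorer,
                           horizon_age=horizon_age) for p in profiles]
    return pd.Series(risks, name=f"lifetime_risk_{sex}")
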