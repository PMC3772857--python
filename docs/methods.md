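# Methods

## The relative-risk model

Case-control status is modelled by logistic regression on categorical risk
factors, with every continuous exposure pre-categorised:

    logit P(case | X) = b0 + b_age'X_age + b_study'X_study + b_sex X_sex
                        + b_smoking'X_smoking + b_diabetes'X_diabetes
                        + b_famhx'X_famhx + b_alcohol'X_alcohol
                        + b_bmi'X_bmi + b_abo'X_abo
                        + b_1q32 G_1q32 + b_5p15 G_5p15 + b_13q22 G_13q22

Indicator vectors leave the reference level out (never smoker, never
diabetic, no family history, <=3 drinks/day, BMI 18.5-25, OO genotype), so
each reference level carries an implicit coefficient of 0.  SNPs enter as
risk-allele counts 0-2 (a log-additive per-allele model).  Missing
non-genetic covariate values are their own level with their own coefficient
(missing-indicator method); subjects missing any *genetic* marker are
excluded from any fit that includes genetic terms (complete-case rule for
genotypes).  Diabetes history gets separate coefficients for prospective
(cohort) and retrospective (case_control) strata, because its estimated
effect differs by design (recall and reverse-causation artefacts in
retrospective studies).

The relative risk of a profile X is `RR(X) = exp(sum of selected
non-nuisance terms)`.  Age, sex and study coefficients are estimated but
quarantined as nuisance: prediction anchors age and sex to registry
incidence instead, so including them in RR would double-count.  The
reference profile maps to exactly 1, and RR is multiplicative across
covariates.

ABO diplotypes are derived from two tag SNPs: the rs505922 allele count o
counts O haplotypes, the rs8176746 allele count b counts B haplotypes, and
the remaining `2 - o - b` haplotypes are A.  `o + b > 2` is inconsistent
(one haplotype cannot carry both tags) and is rejected.

### Fitting

Newton-Raphson/IRLS on the binomial log-likelihood with step-halving to
guarantee ascent.  Convergence when the maximum absolute score falls below
1e-8 or the relative log-likelihood change falls below 1e-10; iteration cap
100.  Rank deficiency is diagnosed up front (naming an offending column)
and apparent separation (|beta| > 30) aborts with the offending term.
All-zero design columns — levels unobserved in the data, e.g. missing
indicators in complete data — are dropped and recorded in the fit
metadata.  The covariance is the inverse observed information at the
optimum.  The test suite cross-checks coefficients and standard errors
against an independent GLM implementation and against the closed-form 2x2
log odds ratio.

Prediction-mode `relative_risk` rejects profiles containing a 'missing'
level — a person using a calculator knows their own covariates — while
`on_missing="score"` restores missing-indicator scoring for internal
validation parity with the fit.

## Absolute risk

Baseline hazard: `rho_sex(t) = incidence_sex(t) / mean RR`, where the mean
is a single sex-specific scalar over complete-data control profiles (not
age-stratified).  This makes the calibration identity exact at every age:
the control-average of `rho_sex(t) RR_i` reproduces the population rate to
machine precision, which the tests assert at 1e-12.

Risk accumulates on an annual grid with half-open age intervals [a1, a2)
and integer attained ages.  Within a year, hazards are constant and the
exact exponential split is used: with disease hazard h and competing
all-cause mortality m,

    P(onset in year t) = h/(h+m) * (1 - exp(-(h+m))) * S(t),
    S(t) = prod_{u<t} exp(-(h(u)+m(u))).

A year with h+m = 0 contributes 0 (the limit convention, not an error).
This choice, rather than the cruder `h * prod(1-h-m)` product, agrees with
it to first order and matches a daily-grid piecewise-constant oracle to
1e-6 relative, which is how the tests pin it down.  The decomposition
disease + death-from-other-causes + event-free survival sums to 1 to 1e-9,
and splitting an interval with survival-weighted recombination is exact.

All-cause mortality is used undecremented for pancreatic-cancer deaths;
at this disease's incidence the double-counting is negligible.  The
lifetime horizon defaults to age 85 and is configurable.  The start age is
a required argument everywhere — whether lifetime risks begin at birth or
at cohort entry is a modelling decision the caller must make explicitly;
the analysis drivers use start age 50, by which age essentially all
incidence lies ahead.

## Evaluation

AUROC is the Mann-Whitney statistic computed from midranks (ties get half
credit), with the DeLong placement-value variance; this equals the grouped
delete-one jackknife, which the tests verify on small instances.  Paired
model comparison uses the DeLong structural-component covariance on the
same subjects.  Reclassification cross-tabulates subjects by (old, new)
category at a threshold, separately for cases and controls, with 'high
risk' strictly greater than the threshold.  The category NRI is

    NRI = (up - down)/n_cases - (up - down)/n_controls,

with the standard large-sample variance and a one-sided upper-tail test of
improvement (two-sided also reported).  Evaluation in the analysis drivers
is restricted to subjects with complete genetic and non-genetic data,
matching the protocol the model was assessed under.

## Winner's curse

For an estimate that was only reported because `|beta_hat|/se >= c` (c the
upper-alpha/2 normal quantile; alpha defaults to genome-wide 5e-8), the
conditional likelihood divides the normal density by the selection
probability `Phi(-c + beta/se) + Phi(-c - beta/se)`.  The conditional MLE
is found by bounded one-dimensional minimization to 1e-12 and checked
against a dense grid search to 1e-6.  It shrinks toward zero, never past
the naive estimate, and the correction vanishes as |beta_hat|/se grows.
Because the conditional MLE systematically overcorrects, a weighted
average of naive and conditional estimates is also reported; the weight is
an exposed parameter (default 0.5 on each) rather than a hard-coded
constant.  Inflation is `100 (beta_hat - beta_adj)/beta_adj` percent.
When demonstrating the adjustment on the packaged odds ratios, standard
errors are back-derived from the published CIs as
`(log U - log L)/(2 * 1.96)`; the discovery-stage standard errors were
never published, so those inflation figures are a qualitative
demonstration, not a reproduction.

## The synthetic-data generator

The generator emulates the pooled consortium's statistical structure:

- **Covariates** are drawn independently per subject from the control-arm
  category frequencies, separately for the cohort and case-control strata
  (stored as raw counts in `synth.py`).  Only marginal frequencies were
  reported, so no between-covariate correlation is induced.
- **Genotypes**: the three SNPs are Hardy-Weinberg draws at the control
  risk-allele frequencies (0.754, 0.446, 0.368); ABO diplotypes are
  unordered pairs of O/A/B haplotypes at frequencies (0.653, 0.267, 0.080)
  derived by direct allele counting from the control diplotype counts, and
  tag-SNP counts are emitted consistently by construction.
- **Disease** is Bernoulli with logit = intercept + beta'x using a
  configurable true coefficient set (the packaged published set by
  default).  The intercept is tuned by bisection so the expected case
  yield over a covariate pool of 3x the requested sample is 1.25x the
  requested cases (no baseline prevalence is stated anywhere, and
  case-control sampling absorbs the intercept); the requested numbers of
  cases and controls are then taken from the realized statuses.  Because
  the sampling conditions only on status, refitting recovers the true odds
  ratios.
- **Missingness** is MCAR per covariate with the stratum-specific observed
  rates (much higher in the retrospective stratum), applied after status
  assignment.  Nuisance (age/sex/study) truths default to zero, mirroring
  the frequency-matched case/control age and sex margins.
- **Life tables** are Gompertz-shaped: incidence
  `a exp(0.07 (t - 60))` above an onset age of 30 (zero below), all-cause
  mortality `m0 exp(g (t - 60))`.  The per-sex anchors are set so that
  integrating the raw incidence to age 85 under competing mortality gives
  ~1.47% (men) and ~1.31% (women), the population lifetime-risk order the
  model is meant to operate at.

What passing tests on these data do and do not show: they verify the
estimators and the pipeline plumbing (coding, fitting, calibration,
integration, metrics) under the model's own assumptions at realistic
frequencies and effect sizes.  They do not capture confounding between
risk factors, linkage disequilibrium beyond the two ABO tags, population
stratification, informative missingness, or secular trends in registry
rates — so agreement here does not certify performance on real cohort
data.  Two visible consequences: the extreme upper tail of lifetime risk
is thinner than with correlated risk factors (the share of male controls
above 5% lifetime risk comes out at ~0-2 per 1,000, versus a few per 1,000
with real data), and the NRI of adding genetics is *positive* on synthetic
data because the generating model is exactly the full model — the observed
near-zero NRI on real data reflects effect sizes and overlap, not a
property the generator encodes.

## Problem sizes and reproducibility

The simulate-and-refit study runs 20 replicates at 3,349 cases / 3,654
controls with complete data; the Hardy-Weinberg property test uses a
50,000-subject null draw; bias-shrinkage checks compare n and 4n at
reduced scale.  All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; replicate seeds are derived via
`SeedSequence` and kept below 2^31.  `scripts/acceptance.py --seed S`
reruns the whole study deterministically for a given S.

## Known limitations

- The packaged coefficient set has no age/sex/study or missing-indicator
  terms (they were never published), so it supports RR(X) scoring of
  complete profiles only, not likelihood evaluation or missing-level
  scoring; refit on data for those uses.
- Published odds ratios differ slightly between the final-model table and
  the running text (e.g. alcohol 1.45 vs 1.37); the packaged set follows
  the final-model table throughout.
- No confidence intervals on absolute risks, no interaction terms, no
  regularization, no continuous-covariate modelling, no family-based
  conditioning for high-penetrance carriers.
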