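# Packaged relative-risk coefficient set: multivariable odds ratios (final model)
# for pancreatic cancer.  Columns: term, odds ratio, 95% CI lower, 95% CI upper.
# Reference levels (never smoker, no diabetes, no family history, <=3 drinks/day,
# BMI 18.5-25, OO genotype, zero risk alleles) have OR 1 and are not listed.
# Diabetes is stratified by study design; no nuisance (age/sex/study) or
# missing-indicator coefficients were published, so this set supports relative
# risk scoring of complete profiles only, not likelihood evaluation.
smoking_former	1.22	1.09	1.37
smoking_current	2.20	1.84	2.62
diabetes_gt3y_cohort	1.62	1.15	2.28
diabetes_unknown_cohort	2.37	1.64	3.44
diabetes_gt3y_cc	1.77	1.37	2.31
diabetes_unknown_cc	1.10	0.80	1.50
famhx_yes	1.60	1.20	2.12
alcohol_yes	1.45	1.19	1.76
bmi_under18_5	0.91	0.54	1.53
bmi_25_30	1.08	0.96	1.22
bmi_over30	1.26	1.09	1.45
abo_AO	1.23	1.10	1.37
abo_AA	1.49	1.24	1.79
abo_BO	1.35	1.15	1.59
abo_BB	1.58	0.97	2.59
abo_AB	1.44	1.15	1.81
snp_1q32	1.29	1.19	1.40
snp_5p15	1.18	1.10	1.26
snp_13q22	1.27	1.18	1.36
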