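# Generator defaults calibrated to the published trial: arm sizes, utility
# means at months 0/2/5 with SD = SE * sqrt(n), per-category cost means/SDs,
# attendance means and ranges, weeks of work inability, and a ~43 % marginal
# utility-nonresponse rate (MAR: rising in secondary-care cost, falling in
# attendance). The general-practice SE is read as 60.42 (the printed 6042
# is a misprint). Attendance dispersion (kappa) and the 0.6 within-patient
# utility correlation are free parameters not fixed by the published tables.
lc:
  label: lc
  n: 413
  utility_means: [0.720, 0.771, 0.788]
  utility_sds: [0.122, 0.122, 0.122]
  interviews: 2
  training_mean: 19.61
  training_range: [1, 24]
  education_mean: 6.46
  education_range: [0, 9]
  attendance_kappa: 1.5
  cost_means:
    general_practice: 1361
    specialist: 252
    physiotherapist: 120
    dentist: 186
    primary_other: 28
    medicine: 2064
    outpatient: 44050
    admissions: 17644
  cost_sds:
    general_practice: 1228
    specialist: 674
    physiotherapist: 576
    dentist: 292
    primary_other: 192
    medicine: 1934
    outpatient: 16258
    admissions: 62123
  week_means:
    reschooling: 0.02
    disability: 2.12
    sick: 2.13
  week_sds:
    reschooling: 0.41
    disability: 6.30
    sick: 6.30
standard:
  label: standard
  n: 412
  utility_means: [0.705, 0.754, 0.782]
  utility_sds: [0.122, 0.122, 0.122]
  interviews: 0
  training_mean: 18.48
  training_range: [1, 24]
  education_mean: 5.97
  education_range: [0, 9]
  attendance_kappa: 1.5
  cost_means:
    general_practice: 1314
    specialist: 234
    physiotherapist: 112
    dentist: 160
    primary_other: 31
    medicine: 2022
    outpatient: 41513
    admissions: 19250
  cost_sds:
    general_practice: 1347
    specialist: 724
    physiotherapist: 528
    dentist: 209
    primary_other: 256
    medicine: 2202
    outpatient: 20674
    admissions: 61459
  week_means:
    reschooling: 0.05
    disability: 1.60
    sick: 2.33
  week_sds:
    reschooling: 1.02
    disability: 5.68
    sick: 6.29
age_mean: 63
age_sd: 10
age_range: [27, 92]
male_frac: 0.76
ihd_frac: 0.79
utility_corr: 0.6
utility_cost_corr: -0.3
utility_support: [0.30, 1.0]
post_followup_admission_frac: 0.10
nonresponse_rate: 0.43
mar_beta_cost: 0.7
mar_beta_attendance: -0.7
pension_age: 67
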