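# Nordic acute-care cohort profile (five hospitals, 2000-2001; n = 763).
# Demographic and priority-level marginals are stored as the published
# counts and normalized at load time; generating odds ratios / hazard
# ratios are the published multivariate point estimates, with intercepts
# and the baseline hazard solved at generation time to match the published
# marginal outcome rates.
name: nordic
profile_n: 763
sex: {woman: 497, man: 266}
age_group: {'75_79': 203, '80_84': 232, '85_89': 210, '90_plus': 118}
lived_alone: 468
prior_hosp_90d: 239
reason: {new_problem: 304, exacerbation: 298, both: 160}
levels:
  premorbid: {low: 301, mild: 79, moderate: 184, high: 151, very_high: 48}
  admission: {low: 91, mild: 65, moderate: 341, high: 193, very_high: 73}
  day7_or_discharge: {low: 176, mild: 101, moderate: 237, high: 181, very_high: 68}
discharge_outcome: {home: 626, institution: 81, dead: 42, other: 14}
one_year_outcome: {home: 426, institution: 79, dead: 202, other: 56}
# Diagnosis-group prevalences are not published; package defaults.
dx_prevalence: {neoplasms: 0.15, mental_behavioral: 0.10, respiratory: 0.20}
outcome_models:
  discharge_home:
    timepoint: premorbid
    marginal_rate: 0.820445  # 626/763
    maple_reference: very_high
    odds_ratios:
      sex_woman: 1.12
      age_80_84: 0.82
      age_85_89: 0.86
      age_90_plus: 0.61
      reason_exacerbation: 1.46
      reason_both: 0.76
      maple_low: 12.20
      maple_mild: 4.23
      maple_moderate: 2.38
      maple_high: 2.08
  adverse_discharge:
    timepoint: day7_or_discharge
    marginal_rate: 0.161206  # 123/763
    maple_reference: low
    odds_ratios:
      sex_woman: 1.13
      age_80_84: 1.27
      age_85_89: 1.17
      age_90_plus: 1.65
      reason_exacerbation: 0.99
      reason_both: 1.41
      maple_mild: 4.22
      maple_moderate: 18.06
      maple_high: 25.09
      maple_very_high: 51.71
  home_one_year:
    timepoint: premorbid
    # rate among one-year survivors: 426/561
    marginal_rate: 0.759358
    conditional_on_survival: true
    maple_reference: very_high
    odds_ratios:
      sex_woman: 1.28
      age_80_84: 1.02
      age_85_89: 0.92
      age_90_plus: 0.67
      reason_exacerbation: 0.79
      reason_both: 0.77
      maple_low: 9.76
      maple_mild: 4.13
      maple_moderate: 3.46
      maple_high: 3.44
survival_model:
  timepoint: premorbid
  one_year_death_rate: 0.264744  # 202/763
  maple_reference: low
  hazard_ratios:
    sex_woman: 0.61
    age_80_84: 1.17
    age_85_89: 1.25
    age_90_plus: 1.52
    reason_exacerbation: 1.46
    reason_both: 1.94
    maple_mild: 1.61
    maple_moderate: 1.76
    maple_high: 2.82
    maple_very_high: 3.70
    dx_neoplasms: 3.21
    dx_mental_behavioral: 0.43
    dx_respiratory: 1.59
censor_day: 365
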