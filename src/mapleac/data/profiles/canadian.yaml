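# Ontario acute-care cohort profile (eight hospitals, 2001; n = 393).
# No one-year follow-up was collected: the survival and one-year outcome
# models are absent, and generated episodes carry a missing one-year
# outcome.  Day-7/discharge level counts sum below profile_n (levels were
# not computable for every episode); normalization uses the column sum.
name: canadian
profile_n: 393
sex: {woman: 234, man: 159}
age_group: {'75_79': 84, '80_84': 119, '85_89': 116, '90_plus': 74}
lived_alone: 117
prior_hosp_90d: 123
reason: {new_problem: 211, exacerbation: 126, both: 56}
levels:
  premorbid: {low: 124, mild: 45, moderate: 88, high: 92, very_high: 44}
  admission: {low: 57, mild: 37, moderate: 119, high: 118, very_high: 62}
  day7_or_discharge: {low: 59, mild: 37, moderate: 105, high: 108, very_high: 69}
discharge_outcome: {home: 197, institution: 109, dead: 46, other: 41}
dx_prevalence: {neoplasms: 0.15, mental_behavioral: 0.10, respiratory: 0.20}
outcome_models:
  discharge_home:
    timepoint: premorbid
    marginal_rate: 0.501272  # 197/393
    maple_reference: very_high
    odds_ratios:
      sex_woman: 1.31
      age_80_84: 0.94
      age_85_89: 0.50
      age_90_plus: 0.29
      reason_exacerbation: 2.26
      reason_both: 0.71
      maple_low: 11.60
      maple_mild: 10.89
      maple_moderate: 5.39
      maple_high: 3.10
  adverse_discharge:
    timepoint: day7_or_discharge
    marginal_rate: 0.394402  # 155/393
    maple_reference: low
    odds_ratios:
      sex_woman: 0.85
      age_80_84: 0.88
      age_85_89: 1.36
      age_90_plus: 2.12
      reason_exacerbation: 0.78
      reason_both: 2.00
      maple_high: 4.83
      maple_very_high: 11.07
censor_day: 365
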