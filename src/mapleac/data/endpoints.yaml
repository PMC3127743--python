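# Default binary-endpoint definitions for the validation battery.
# Each outcome category maps to exactly one disposition; the "other"
# category is negative on both sides, matching the published model
# denominators.  maple_reference is the priority level reported as 1.00.
discharged_home:
  outcome_field: discharge_outcome
  positive: [home]
  negative: [institution, dead, other]
  maple_reference: very_high
adverse_at_discharge:
  outcome_field: discharge_outcome
  positive: [institution, dead]
  negative: [home, other]
  maple_reference: low
home_at_one_year:
  outcome_field: one_year_outcome
  positive: [home]
  negative: [institution, dead, other]
  maple_reference: very_high
adverse_at_one_year:
  outcome_field: one_year_outcome
  positive: [institution, dead]
  negative: [home, other]
  maple_reference: low
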