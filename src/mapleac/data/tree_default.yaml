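# Reference encoding of the MAPLe-AC decision tree.
#
# Rules are evaluated top-down, first match wins; the default level applies
# when no rule fires.  Conditions are restricted boolean expressions over
# the classifier-vector fields: adl, cps (0-6 subscale scores), the boolean
# flags behavior, decision_decline, medication_problem, pressure_ulcer,
# fall, meal_prep_problem, swallowing_difficulty, the institutional-risk
# screener (inst_risk_count 0-8, inst_risk_active = count >= 3), and the
# geriatric screener subscore (screener, 0-6).
#
# This encoding exercises every classifier and is monotone: raising any
# single component never lowers the assigned level.  It is a reference
# encoding, overridable without code changes; its version string is carried
# into all output provenance.
version: mapleac-tree-0.1-reference
default_level: low
rules:
  - name: severe_impairment_with_institutional_risk
    level: very_high
    when: "inst_risk_active and (adl >= 4 or cps >= 4 or behavior)"
  - name: major_impairment_or_active_risk
    level: high
    when: "adl >= 3 or cps >= 3 or behavior or pressure_ulcer or inst_risk_active"
  - name: clinical_findings_or_mild_impairment
    level: moderate
    when: "fall or swallowing_difficulty or medication_problem or decision_decline or adl >= 1 or cps >= 1"
  - name: isolated_screener_findings
    level: mild
    when: "screener >= 1 or meal_prep_problem"
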