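# MAPLe-AC crosswalk codebook: the 31 acute-care assessment items consumed
# by the algorithm's classifiers.  "consumer" is the primary classifier an
# item feeds (items may additionally feed other classifiers, e.g. eating
# also enters the CPS; the many-to-many view lives in the package registry).
version: mapleac-codebook-0.1
items:
  # --- ADL self-performance (0 independent .. 6 total dependence; 8 = activity did not occur)
  - {code: adl_hygiene,        group: adl, consumer: adl_hierarchy, domain: [0,1,2,3,4,5,6,8], label: "Personal hygiene self-performance"}
  - {code: adl_toilet_use,     group: adl, consumer: adl_hierarchy, domain: [0,1,2,3,4,5,6,8], label: "Toilet use self-performance"}
  - {code: adl_locomotion,     group: adl, consumer: adl_hierarchy, domain: [0,1,2,3,4,5,6,8], label: "Locomotion self-performance"}
  - {code: adl_eating,         group: adl, consumer: adl_hierarchy, domain: [0,1,2,3,4,5,6,8], label: "Eating self-performance"}
  # --- Cognition
  - {code: comatose,                  group: cognition, consumer: cps, domain: [0,1],       label: "Comatose / no discernible consciousness"}
  - {code: short_term_memory_problem, group: cognition, consumer: cps, domain: [0,1],       label: "Short-term memory problem"}
  - {code: decision_making,           group: cognition, consumer: cps, domain: [0,1,2,3],   label: "Cognitive skills for daily decision making (0 independent .. 3 severely impaired)"}
  - {code: making_self_understood,    group: cognition, consumer: cps, domain: [0,1,2,3],   label: "Making self understood (0 understood .. 3 rarely/never)"}
  # --- Behavior disturbance
  - {code: verbally_abusive,        group: behavior, consumer: behavior, domain: [0,1], label: "Verbally abusive behavior"}
  - {code: physically_abusive,      group: behavior, consumer: behavior, domain: [0,1], label: "Physically abusive behavior"}
  - {code: socially_inappropriate,  group: behavior, consumer: behavior, domain: [0,1], label: "Socially inappropriate behavior"}
  - {code: resists_care,            group: behavior, consumer: behavior, domain: [0,1], label: "Resists care"}
  # --- Clinical flags
  - {code: decision_making_decline,       group: clinical, consumer: decision_decline,      domain: [0,1], label: "Decline in decision making"}
  - {code: medication_management_problem, group: clinical, consumer: medication_problem,    domain: [0,1], label: "Problem managing medications"}
  - {code: pressure_ulcer,                group: clinical, consumer: pressure_ulcer,        domain: [0,1], label: "Pressure ulcer present"}
  - {code: fall_recent,                   group: clinical, consumer: fall,                  domain: [0,1], label: "Recent fall"}
  - {code: meal_preparation_problem,      group: clinical, consumer: meal_prep_problem,     domain: [0,1], label: "Problem with meal preparation"}
  - {code: swallowing_difficulty,         group: clinical, consumer: swallowing_difficulty, domain: [0,1], label: "Difficulty swallowing"}
  # --- Nursing-home (institutional) risk categories
  - {code: prior_nursing_home,          group: risk, consumer: inst_risk, domain: [0,1], label: "Prior nursing home placement"}
  - {code: goes_out,                    group: risk, consumer: inst_risk, domain: [0,1], label: "Goes out of the house (risk fires when homebound)"}
  - {code: bladder_incontinence,        group: risk, consumer: inst_risk, domain: [0,1], label: "Bladder incontinence"}
  - {code: dementia,                    group: risk, consumer: inst_risk, domain: [0,1], label: "Any dementia"}
  - {code: alzheimers,                  group: risk, consumer: inst_risk, domain: [0,1], label: "Alzheimer's disease"}
  - {code: multiple_sclerosis,          group: risk, consumer: inst_risk, domain: [0,1], label: "Multiple sclerosis"}
  - {code: head_trauma,                 group: risk, consumer: inst_risk, domain: [0,1], label: "Head trauma"}
  - {code: hygiene_or_bathing_problem,  group: risk, consumer: inst_risk, domain: [0,1], label: "Problem with hygiene or bathing"}
  - {code: delirium_indicator,          group: risk, consumer: inst_risk, domain: [0,1], label: "Indicator of delirium (acute change in mental status)"}
  - {code: meal_shopping_problem,       group: risk, consumer: inst_risk, domain: [0,1], label: "Problem with meals and shopping activities"}
  # --- Geriatric screener (IADL capacity; the home-care stamina item has no
  #     acute-care counterpart and is structurally absent)
  - {code: phone_use_problem,          group: screener, consumer: screener, domain: [0,1], label: "Problem using the telephone"}
  - {code: housework_problem,          group: screener, consumer: screener, domain: [0,1], label: "Problem with ordinary housework"}
  - {code: finance_management_problem, group: screener, consumer: screener, domain: [0,1], label: "Problem managing finances"}
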