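# Base-case inputs for the nurse-specialist continence-care model.
# All costs are 2013 euros; probabilities are per model cycle (3 months)
# unless the name says yearly. Percentages from the source tables are
# written as decimal fractions (decimal commas normalised to points).

population:
  n_community_elderly: 2591357      # community-dwelling Dutch 65+
  multimorbid_share: 0.31           # display value; n_eligible is authoritative
  n_eligible: 808503                # 65+ with >=4 chronic diseases
  ui_incidence_yearly: 0.032
  ui_prevalence: 0.25
  n_prevalent: 58306
  prevalent_female_share: 0.77

settings:
  cycle_length_years: 0.25
  horizon_cycles: 12
  warmup_cycles: 4                  # 1 year, used to derive the prevalent pool
  implementation_share: 0.238       # share of NS training cost carried by this population
  discount_rate: 0.0
  nursing_home_exit_yearly: 0.04
  use_rounded_uti: false            # true books the display value 8% per cycle

pathway_current:
  detection_incident: 0.504
  assess_gp: 0.95
  assess_ppt: 0.05
  strategy_cure: 0.37
  strategy_containment: 0.61
  strategy_self: 0.02
  gp_immediate_referral: 0.51       # also the referral probability after a failed GP attempt
  gp_referral_to_ppt: 0.57
  gp_referral_to_specialist: 0.43
  gp_rx_medication: 0.79
  gp_medication_improvement: 0.63
  gp_medication_success: 0.16
  gp_rx_lifestyle: 0.17
  gp_lifestyle_improvement: 0.10
  gp_lifestyle_success: 0.0
  gp_rx_uti: 0.04
  gp_uti_improvement: 0.40
  gp_uti_success: 0.10
  gp_rx_training: 0.0
  gp_training_improvement: 0.0
  gp_training_success: 0.0
  medication_second_cycle: 0.76
  medication_continue_improvement: 0.80
  medication_continue_success: 0.20
  ppt_rx_pfmt: 0.95
  ppt_pfmt_improvement: 0.62
  ppt_pfmt_success: 0.0
  ppt_rx_biofeedback: 0.05
  ppt_biofeedback_improvement: 0.45
  ppt_biofeedback_success: 0.23
  training_continue: 1.0
  training_second_improvement: 0.44
  training_second_success: 0.56
  ppt_failure_referral: 1.0
  ppt_referral_to_gp: 0.33
  ppt_referral_to_specialist: 0.67
  specialist_to_ppt: 0.40
  specialist_treat: 0.60
  specialist_rx_surgery: 0.17
  specialist_surgery_improvement: 0.08
  specialist_surgery_success: 0.77
  specialist_rx_conservative: 0.02
  specialist_conservative_improvement: 0.34
  specialist_conservative_success: 0.0
  specialist_rx_medication: 0.81
  specialist_medication_improvement: 0.63
  specialist_medication_success: 0.16
  specialist_failure_referral: 1.0
  specialist_referral_to_gp: 1.0
  specialist_referral_to_ppt: 0.0
  prevalent_cure_gp: 0.3333333333333333
  prevalent_cure_ppt: 0.3333333333333333
  prevalent_cure_specialist: 0.3333333333333333

pathway_new:
  ns_detection_gain: 0.136          # incident detection = current + gain = 0.640
  extra_detection: 0.14             # share of the prevalent cohort newly detected by the NS
  assess_gp: 0.0
  assess_ppt: 0.0
  strategy_cure: 0.39
  strategy_containment: 0.61
  strategy_self: 0.0
  ns_initial_share: 0.96            # initial NS treatment package (three consultations)
  ns_initial_improvement: 0.21
  ns_initial_success: 0.31
  ns_rx_uti: 0.04
  ns_uti_improvement: 0.80
  ns_uti_success: 0.20
  ns_failure_continue: 0.40         # cycle-1 NS failures continuing with NS medication
  ns_rx_medication: 1.0
  ns_medication_improvement: 0.63
  ns_medication_success: 0.16
  ns_medication_second_cycle: 0.76
  ns_medication_continue_improvement: 0.80
  ns_medication_continue_success: 0.20
  ns_failure_referral: 0.60
  ns_referral_to_ppt: 0.33
  ns_referral_to_specialist: 0.67
  ppt_pfmt_improvement: 0.37
  training_second_improvement: 0.46
  training_second_success: 0.54

adverse_events:
  uti_yearly_oab: 0.457             # yearly incidence of >=1 UTI, overactive bladder
  uti_yearly_background: 0.154      # same, no overactive bladder
  fall_per_cycle: 0.0041            # falls attributable to incontinence per cycle
  fracture_given_fall: 0.057
  skin_per_cycle: 0.08

care_use:
  informal_care_share: 0.43
  formal_care_share: 0.47
  care_reduction_improvement: 0.10
  care_reduction_success: 0.25

costs:
  consult_gp: 30.48
  consult_ns: 41.39
  medication_gp_ns: 114.96
  lifestyle_gp: 30.48
  training_gp: 30.48
  uti_treatment_gp_ns: 2.51
  consult_ppt: 39.19
  pfmt_ppt: 205.73
  biofeedback_ppt: 216.23
  consult_specialist: 130.62
  surgery_specialist: 317.97
  medication_specialist: 317.16
  conservative_specialist: 137.74
  pads_success: 0.0
  pads_improvement: 71.22
  pads_failure: 97.70
  uti_event: 2.51
  fracture_event: 2944.36
  skin_event: 6.49
  formal_care_failure: 3859.38
  travel_gp_ns: 3.51
  travel_ppt: 13.94
  travel_specialist: 4.79
  informal_care_failure: 2128.99
  oop_pads: 97.70
  implementation_annual: 426496.0
  ns_monthly_salary: 3728.0
  ns_workable_hours_yearly: 1540.0

utilities:
  utility_success: 0.8595
  utility_incontinent: 0.8246
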