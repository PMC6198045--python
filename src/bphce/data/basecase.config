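# Reference base-case configuration (2018 US$; per-cycle probabilities).
# Every key restates the package default, so loading this file is
# identical to loading an empty document.

transitions.p_bph_stay: 0.345
transitions.p_bph_to_turp: 0.021
transitions.p_bph_to_aur: 0.004
transitions.p_aur_to_turp: 0.8
transitions.p_turp_30day_mortality: 0.0237
transitions.p_turp_to_medical: 0.059
transitions.p_turp_to_repeat: 0.059
transitions.p_repeat_turp_mortality: 0.0
transitions.p_recovery_stay: 0.329
transitions.p_recovery_to_medical: 0.0467
transitions.p_medical_to_second_turp: 0.036
transitions.p_medical_stay: 0.393
transitions.p_medical_to_aur: 0.0
transitions.p_repeat_to_medical: 0.0025
transitions.p_turp_full_recovery: 0.998

efficacy.rrr_aur: 0.676
efficacy.rrr_turp: 0.706

costs.annual_drug_combination: 464.97
costs.annual_drug_tamsulosin: 55.79
costs.annual_bph_management: 471.0
costs.aur_episode: 1312.0
costs.turp_procedure: 6334.0
costs.annual_medical_intervention: 371.0
costs.recovery_followup: 0.0

utilities.u_bph: 0.876
utilities.u_aur: 0.25
utilities.u_turp: 0.25
utilities.u_medical: 0.25
utilities.u_recovery: 1.0
utilities.u_death: 0.0

settings.discount_rate: 0.03
settings.horizon_years: 4
settings.cycles_per_year: 1
settings.cohort_start_age: 66
settings.n_microsim_patients: 10000
settings.probability_timescale: annual
settings.residual_mode: residual
settings.half_cycle_correction: false

lifetable.calibration_target: 0.055
lifetable.slope: 0.09

# one-way sensitivity ranges (95% uncertainty intervals)
range.transitions.p_bph_stay: [0.248, 0.45]
range.transitions.p_bph_to_turp: [0.0098, 0.036]
range.transitions.p_aur_to_turp: [0.75, 0.85]
range.transitions.p_turp_30day_mortality: [0.0179, 0.0296]
range.transitions.p_recovery_stay: [0.275, 0.41]
range.transitions.p_recovery_to_medical: [0.0295, 0.0744]
range.transitions.p_medical_to_second_turp: [0.0215, 0.061]
range.transitions.p_medical_stay: [0.378, 0.438]
range.transitions.p_turp_full_recovery: [0.978, 1.0]
range.transitions.p_bph_to_aur: [0.00064, 0.0154]
range.efficacy.rrr_aur: [0.527, 0.778]
range.efficacy.rrr_turp: [0.577, 0.795]
range.costs.annual_drug_combination: [348.0, 581.0]
range.costs.annual_drug_tamsulosin: [41.8, 69.7]
range.costs.annual_bph_management: [223.0, 720.0]
range.costs.aur_episode: [590.0, 4199.0]
range.costs.turp_procedure: [4549.0, 8119.0]
range.costs.annual_medical_intervention: [123.0, 620.0]
range.utilities.u_bph: [0.83, 0.92]
range.utilities.u_aur: [0.24, 0.26]
range.utilities.u_turp: [0.24, 0.26]
range.utilities.u_medical: [0.24, 0.26]
range.utilities.u_recovery: [0.95, 1.0]
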