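# PSA sampling distributions: beta for probabilities and relative risk
# reductions, gamma for costs.  Gamma rates are rederived from the
# published means (shape / mean) because the printed rate constants are
# inconsistent with the printed means; the printed shapes are kept so
# the intended dispersion ordering is preserved.

dist.transitions.p_bph_to_turp: {family: beta, alpha: 0.62, beta_or_rate: 29.27}
dist.transitions.p_recovery_stay: {family: beta, alpha: 2.83, beta_or_rate: 7.79}
dist.transitions.p_recovery_to_medical: {family: beta, alpha: 2.24, beta_or_rate: 27.97}
dist.transitions.p_medical_to_second_turp: {family: beta, alpha: 2.3, beta_or_rate: 35.16}
dist.transitions.p_bph_to_aur: {family: beta, alpha: 0.06, beta_or_rate: 2.9}
dist.efficacy.rrr_aur: {family: beta, alpha: 1.77, beta_or_rate: 0.85}
dist.efficacy.rrr_turp: {family: beta, alpha: 2.5, beta_or_rate: 1.04}
dist.costs.annual_bph_management: {family: gamma, alpha: 3.61, beta_or_rate: 0.01, mean: 471.0}
dist.costs.aur_episode: {family: gamma, alpha: 0.21, beta_or_rate: 1.57, mean: 1312.0}
dist.costs.turp_procedure: {family: gamma, alpha: 12.59, beta_or_rate: 0.002, mean: 6334.0}
dist.costs.annual_medical_intervention: {family: gamma, alpha: 2.24, beta_or_rate: 0.006, mean: 371.0}
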