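# No causal effect, no confounding, no pleiotropy on the instruments:
# every MR estimator should be null-centred and nominally calibrated.
name: null_scenario
n_individuals: 20000
n_exposure_snps: 100
n_outcome_snps: 24
maf_low: 0.05
maf_high: 0.45
exposure_mean: 25.0
exposure_sd_total: 4.5
exposure_h2_instruments: 0.02
outcome_snp_logodds_low: 0.12
outcome_snp_logodds_high: 0.30
confounder_effect_x: 0.0
confounder_effect_y: 0.0
causal_or_per_unit: 1.0
baseline_prevalence: 0.05
instrument_pleiotropy_mode: none
instrument_pleiotropy_logodds: 0.0
reverse_beta_kgm2: 0.0
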