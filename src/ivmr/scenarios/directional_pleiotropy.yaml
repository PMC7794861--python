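# All exposure instruments carry the same positive direct log-odds effect on
# the outcome (directional horizontal pleiotropy): IVW is biased upward while
# the MR-Egger intercept should detect the violation and its slope stay near
# the true causal effect. Instruments are strong here (10% of exposure
# variance, per-SNP F ~ 20): Egger regression is a strong-instrument
# sensitivity analysis and this preset is its stress test.
name: directional_pleiotropy
n_individuals: 20000
n_exposure_snps: 100
n_outcome_snps: 24
maf_low: 0.05
maf_high: 0.45
exposure_mean: 25.0
exposure_sd_total: 4.5
exposure_h2_instruments: 0.10
outcome_snp_logodds_low: 0.12
outcome_snp_logodds_high: 0.30
confounder_effect_x: 1.0
confounder_effect_y: 0.4
causal_or_per_unit: 1.05
baseline_prevalence: 0.05
instrument_pleiotropy_mode: directional
instrument_pleiotropy_logodds: 0.05
reverse_beta_kgm2: 0.0
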