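# Direct SNP->outcome effects centred on zero (balanced pleiotropy):
# per-SNP estimates are heterogeneous but the average pleiotropy is null,
# so the MR-Egger intercept should not signal and IVW stays consistent.
# Instruments strong (10% of exposure variance), matching the directional
# preset so the two differ only in the pleiotropy pattern.
name: balanced_pleiotropy
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
instrument_pleiotropy_mode: balanced
instrument_pleiotropy_logodds: 0.05
reverse_beta_kgm2: 0.0
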