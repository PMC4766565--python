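# Example run configuration: simulated three-stratum cohort, full pipeline.
# Every protocol threshold is a named key; the values below are the defaults.
simulate:
  n_per_stratum: 2000
  # causal_bp: map              # which BP phenotype carries the causal effect
  # causal_effect_crae: -0.26   # μm per mmHg
  # causal_effect_crve: -0.09
  # pleiotropy_effect: 0.0      # μm per SD of true GRS (direct path)
  # missing_genotype_rate: 0.02

qc_call_rate: 0.95
qc_maf: 0.001
qc_hwe_p: 1.0e-6
grs_window_kb: 100
grs_missing_policy: impute      # or complete_case
grs_weight_mode: in_sample      # or split_sample
n_pcs: 5
scale_per: 10                   # report β per 10 mmHg
model3_mode: meta               # per-ethnicity 2SLS pooled by meta-analysis
model2_covariates: methods      # or footnote
meta_method: fixed              # or random (DerSimonian-Laird)
diabetes_glucose: 11.1
knudtson_arteriole: 0.88
knudtson_venule: 0.95

seed: 1
out_dir: demo
log_level: INFO
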