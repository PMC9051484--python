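# End-to-end demo: simulate a twin cohort whose phenotype follows a
# one-factor common pathway (74% heritable factor), preprocess it and run
# the model-selection pipeline.
true_model:
  kind: cp1
  factor_a: 0.86
  loadings: 0.8
  residual_a: 0.3
  residual_e: 0.45
cohort:
  n_mz_pairs: 500
  n_dz_pairs: 500
  n_incomplete_pairs: 100
  participation: 0.85
covariates: [scanner, age, ethnicity, cohort]
components: AE
n_starts: 3
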