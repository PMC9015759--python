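# Default cohort-selection criteria with a shipped *synthetic* vocabulary.
#
# Real terminologies (ICD-10, RxNorm, CPT) are licensed and the published
# criteria do not print code lists, so the defaults use synthetic codes that
# the bundled data generator emits. Each set is configuration: swap in real
# code lists for real extracts.

frequent_ed_threshold: 2

code_sets:
  # diagnoses
  asthma_dx: ["DX:ASTHMA"]
  respiratory_dx: ["DX:RESP-BRONCHITIS", "DX:RESP-WHEEZE", "DX:RESP-URI"]
  pulmonary_dx: ["DX:PULM-COPD", "DX:PULM-FIBROSIS"]
  # medications typically used to treat asthma
  asthma_med: ["MED:ALBUTEROL-INH", "MED:FLUTICASONE", "MED:MONTELUKAST"]
  # tests/procedures typically used to manage asthma (includes lab measures)
  asthma_proc: ["PROC:SPIROMETRY", "PROC:FENO"]
  # nebulizer treatments administered during ED visits
  nebulizer_med: ["MED:ALBUTEROL-NEB"]
  # outcome counting: respiratory-issue diagnoses and oral prednisone
  respiratory_visit_dx: ["DX:ASTHMA", "DX:RESP-BRONCHITIS", "DX:RESP-WHEEZE",
                         "DX:RESP-URI", "DX:PULM-COPD", "DX:PULM-FIBROSIS"]
  prednisone_med: ["MED:PREDNISONE"]
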