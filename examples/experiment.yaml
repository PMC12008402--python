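# Desk-scale synthetic experiment: curated vs comprehensive cohorts.
gen:
  n_patients: 60
  eyes_per_patient: 1
  volume_shape: [64, 64, 32]
  exams_per_eye: 5
  test_retest_sd_db: 1.5
  eyelid_artifact_rate: 0.1
  seed: 7
train:
  input_shape: [64, 64, 32]
  seed: 7
outdir: scratch/experiment
folds_to_run: 1
log_level: INFO
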