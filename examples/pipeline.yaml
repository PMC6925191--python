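# End-to-end pipeline configuration: simulate a small cohort, build the
# minimal-sensor feature matrix, and evaluate 2-stage LOSO staging.
seed: 1
output_dir: somnostage_out
simulate:
  n_subjects: 4
  duration: 2.0        # hours per night
  ecg_rate: 250.0      # Hz; the device path uses 1000
features:
  subset: minimal      # non-dominant wrist accel + ECG + hand temperature
staging:
  resolution: 2        # wake vs sleep
  mode: loso
  n_trees: 130
  undersample: true
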