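# Pipeline configuration (see boundedplan.pipeline)
cohort:
  alpha0: 0.1
  alpha1: 1.0
  alpha2: 0.5
  beta1: 500.0
  beta2: 500.0
  hypothesis: H1_prospective
  link: linear
  n_subjects: 5
  n_trials: 120
  noise_sd: 0.05
fitting:
  links:
  - linear
  n_shuffles: 200
grid:
  beta1_values:
  - 5.0
  - 500.0
  beta2_values:
  - 5.0
  - 500.0
output_dir: runs/smoke
seed: 7
solver:
  max_iter: 5000
  tol: 1.0e-10
task:
  conditions:
  - - '1'
    - 2
  - - '11'
    - 2
  - - '2'
    - 2
  n_panels: 2
  offsets_per_half:
    '2':
    - - 1
      - 1
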