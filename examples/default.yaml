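# Pipeline configuration (see boundedplan.pipeline)
cohort:
  alpha0: 0.1
  alpha1: 0.05
  alpha2: 0.01
  beta1: 20.0
  beta2: 20.0
  hypothesis: H1_prospective
  link: linear
  n_subjects: 19
  n_trials: 120
  noise_sd: auto
fitting:
  links:
  - linear
  n_shuffles: 2000
grid:
  beta1_values:
  - 2.0
  - 20.0
  - 500.0
  beta2_values:
  - 2.0
  - 20.0
  - 500.0
output_dir: runs/default
seed: 1
solver:
  max_iter: 3000
  tol: 1.0e-09
task: {}
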