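# Demo: synthetic liver cohort, five groups, full pipeline.
out: demo_out
simulate:
  matrix: liver
  groups:
    - {label: control, n: 5}
    - {label: model, n: 5}
    - {label: low, n: 5}
    - {label: medium, n: 5}
    - {label: high, n: 5}
  seed: 7
excise:
  - [4.54, 5.18]
binning:
  min_width: 0.01
  max_width: 0.12
  min_prominence: 0.05
pqn:
  reference: median-all
assignments: default
contrasts:
  - [model, control]
  - [low, model]
  - [medium, model]
  - [high, model]
opls:
  n_orth: 1
  repeats: 5
  n_perm: 0
  seed: 7
network:
  threshold: 0.6
  reactions: default
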