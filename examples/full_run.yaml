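# Full synthetic pipeline: simulate a shifted two-species cohort, preprocess,
# train the adversarial broad-type classifier, and report per-domain metrics.
seed: 0
stages: [simulate, preprocess, train_dann, evaluate]

simulate:
  composition: binary          # the study's 700/724 mouse, 231/68 human
  effect_size: 3.0
  noise_sd: 1.0
  missing_rate: 0.0
  shift:
    offset_sd: 1.5             # random per-feature affine shift on humans
    domain: human

preprocess:
  fractions: [0.6797, 0.1201, 0.2002]   # -> 1171 / 207 / 345
  stratify_on: [organism, broad_label]

train_dann:
  hidden_layers: [64, 32, 16]
  activation: relu
  lambda_: 1.0
  learning_rate: 0.05
  batch_size: 64
  epochs: 400
  optimizer: sgd
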