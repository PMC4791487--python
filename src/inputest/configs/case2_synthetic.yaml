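# Energy-intake estimation from body-mass measurements (Guo-Hall
# energy-partitioning model, DIO-mouse scale), on a synthetic surrogate of
# the group-mean design: day -9, then daily / every 2 days to day +30.
# Model parameter values are supplement-derived placeholders: synthetic,
# self-consistent values standing in for the published ones.
model:
  name: guo_hall
  params: {}            # defaults = placeholder values in dynamics.py
dataset:
  synthetic: case2_group
  seed: 1
basis:
  kind: kl              # Karhunen-Loeve modes of the first-derivative prior
  n_basis: 20
  penalty_order: 1      # random-walk prior on the energy intake
  augmentation: constant  # unpenalised offset so EI can start nonzero
  grid_size: 400
scale: linear
noise:
  kind: proportional
  sigma: 0.005          # 0.5 % proportional measurement noise
prior:
  kind: derivative
  penalty_order: 1
tau:
  strategy: bayes       # tau sampled by Gibbs under Gamma(0.001, 0.001)
  a0: 0.001
  b0: 0.001
sampler:
  scheme: smmala_gibbs  # alternate Gibbs tau-update and joint SMMALA theta-update
  n_samples: 5000
  seed: 0
outputs: results/case2_synthetic
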