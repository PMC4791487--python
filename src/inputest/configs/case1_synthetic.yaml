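# Oral-absorption input estimation on the eflornithine PK model,
# run on a synthetic surrogate of the low-dose series (dense early sampling
# around the concentration peak, sparse late decline).
# Model parameter values are supplement-derived placeholders: synthetic,
# self-consistent values standing in for the published ones.
model:
  name: eflornithine
  params: {}            # defaults = placeholder values in dynamics.py
dataset:
  synthetic: case1_low  # 20 mg dose, additive noise
  seed: 1
basis:
  kind: bspline         # cubic B-splines, breakpoints at measurement times
  degree: 3
scale: log              # prior on ln u(t); u > 0 by construction
noise:
  kind: additive        # assumed form; sigma configurable
  sigma: 0.004          # mg/L, ~1.5 % of the low-dose peak
prior:
  kind: derivative
  penalty_order: 2
tau:
  strategy: l_curve     # pick the corner, keep one neighbour on each side
sampler:
  scheme: componentwise # per-coefficient RWMH with 0.2-0.5 acceptance tuning
  n_samples: 15000
  seed: 0
dose: 20.0              # enables the bioavailability posterior
outputs: results/case1_synthetic
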