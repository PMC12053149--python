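name: paper_default
n_animals: 11
seed: 0
params:
  alpha: 0.4
  beta: 5.0
  delta: 0.5
cno_effect:
  beta_scale: 0.6
  delta_shift: -1.0
jitter:
  alpha: 0.05
  beta_rel: 0.2
  delta: 0.3
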