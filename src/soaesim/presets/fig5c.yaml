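N: 110
freq_exponent_denominator: 110
mu_ratio: 5.0
alpha_profile:
  kind: disordered
  disorder_sd: 0.03
  disorder_seed: null
beta: 0.0
gamma: 1.0
delta: 0.0
F: 0.0
stimulus_phase: 0.0
noise:
  sd: 0.1
  update_interval: 0.016
  seed: null
seed: 0
t_total: 3360.0
t_equilibrate: 160.0
sample_interval: 0.016
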