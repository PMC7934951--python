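# Control-condition configuration (the package defaults, written out).
# Pass to the CLI with --config; individual flags still override.
vegf:
  mode: gradient        # gradient | uniform
  V: 0.04               # slope per site (gradient) or flat value (uniform)
  sensing_scale: 3.0
vessel:
  n_cells: 10
  radius_um: 3.0
  cell_width_um: 10.0
signalling:
  sigma: 12.0
  delta: 1.35
  delay_steps: 28
  vegfr_max: 12000.0
  notch_max: 50.0
  d_max: 10000.0
  dll4_mode: accumulate
filopodia:
  F: 2.0
  G: 0.9
  filtipmax: 15
  token_strength: 1.0
  filspacing: 2
  init_factor: 0.01
  actin_pool_um: 300.0
  max_length_um: 30.0
pattern:
  min_tips: 4
  max_tips: 5
  stability_window: 100
  dll4_advantage: 600.0
  dll4_window: 100
  max_steps_gradient: 2000
  max_steps_uniform: 5000
hysteresis:
  d_ext_step: 50.0
  transient_steps: 250
  window: 250
  epsilon: 0.5
  max_steps_per_level: 60000
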