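# Example sweep: 10 configurations per segment, all three estimators.
seed: 1
n_configs: 10
segments: [thigh, shank]
estimators: [pct, pctpt, svdls]
sta_mode: synthetic
sta_amplitude: {thigh: 0.012, shank: 0.005}
sta_harmonics: 3
gait:
  cycle_duration: 1.0
  n_cycles: 3
  sample_rate: 240.0
  stance_fraction: 0.6
d_max: 0.01
save_trajectories: false
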