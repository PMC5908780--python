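# Example hfovbench configuration: a reduced noiseless study-2 grid.
schema: hfovbench-config-v1
seed: 42

settings:
  frequency: 8.0
  map_pressure: 25.0
  fio2: 0.21
  insp_fraction: 0.5

lung:
  container_volume: 20.0    # L
  dead_space: 110.0         # mL
  airway_resistance: 2.0    # cmH2O/L/s (metadata)
  vco2_insufflation: 200.0  # mL/min
  capno_sample_flow: 200.0  # mL/min

gas:
  barometric_pressure: 760.0  # mmHg

mixing:
  effective_bf_fraction: 1.0

sim:
  flow_sample_rate: 200.0
  capno_sample_rate: 10.0
  capno_time_constant: 2.0
  flow_noise_sd: 5.0   # mL/s
  pco2_noise_sd: 0.2   # mmHg
  duration: 240.0      # s

grid:
  study: 2
  sv_values: [80.0, 100.0, 120.0]
  bf_values: [10.0, 20.0, 30.0, 40.0, 50.0, 60.0]
  replicates: 5

stabilization:
  window: 60.0
  max_rel_slope: 0.01  # fraction per minute
  min_elapsed: 120.0
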