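# A small exploration: WPD-based spotting on the ARM CortexM3 in
# real-time mode, uniform vs context-adaptive sampling at two
# sensitivity settings, over synthetic participants.
design_space:
  functionalities:
    - id: algorithm
      components:
        - id: wpd
          parameters: {m: [1.0], d: [20]}
    - id: sampling
      components:
        - id: uniform
        - id: adaptive
          parameters: {theta_high: [60.0, 180.0]}
    - id: mcu
      components:
        - id: arm_cortex_m3
    - id: runtime
      components:
        - id: real_time
requirements:
  min_precision: 0.7
  min_recall: 0.8
  energy_budget_mwh: null   # derived from the battery: BC/RT*phi
sampler:
  d_low: 0.1
  d_high: 1.0
  d_threshold: 0.6
  theta_low: 10.0
  n_shots: 4
  tau: 3.0
  period: 1.0
generator:
  n_participants: 3
  duration: 1800.0
  n_events: 3
  event_duration_range: [120.0, 300.0]
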