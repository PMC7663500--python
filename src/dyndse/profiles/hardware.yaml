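# Component electrical characteristics and per-operation machine cycles,
# taken field-for-field from the component datasheet values used in the
# EMG-eyeglasses case study.  Units: clock_hz Hz, currents mA (memory
# write current in uA), voltage V, memory bytes, t_write_ms ms,
# battery capacity mWh, runtime h.
microcontrollers:
  psoc1_m8c:
    name: PSoC1 M8C
    cycles: {add: 544, mult: 560, div: 912, root: 1344, comp: 80, exp: 2672}
    clock_hz: 24.0e+6
    i_act_ma: 8.0
    i_stb_ma: 0.025
    voltage: 3.3
    resolution_bits: 8
    ram_bytes: 2000
    flash_bytes: 32000
    mem_block_bytes: 64
    i_write_ua: 619.5
    t_write_ms: 1.5
  msp430f1611:
    name: TI MSP430F1611
    cycles: {add: 177, mult: 153, div: 405, root: 668, comp: 37, exp: 334}
    clock_hz: 8.0e+6
    i_act_ma: 0.57
    i_stb_ma: 0.05
    voltage: 3.0
    resolution_bits: 16
    ram_bytes: 10000
    flash_bytes: 48250
    mem_block_bytes: 60
    i_write_ua: 2300.0
    t_write_ms: 23.0
  arm_cortex_m3:
    name: ARM CortexM3
    cycles: {add: 60, mult: 50, div: 80, root: 380, comp: 12, exp: 210}
    clock_hz: 48.0e+6
    i_act_ma: 7.0
    i_stb_ma: 0.55
    voltage: 3.3
    resolution_bits: 32
    ram_bytes: 96000
    flash_bytes: 512000
    mem_block_bytes: 256
    i_write_ua: 500.0
    t_write_ms: 3.28
sensor:
  name: EMG sensing
  i_act_ma: 4.0
  i_stb_ma: 0.008
  voltage: 3.3
radio:
  name: BLE
  i_trans_ma: 21.7
  t_trans_ms: 16.0
  packet_bytes: 114
  mps_bits: 216
  conn_interval_ms: 7.5
battery:
  name: Li-Ion polymer battery
  capacity_mwh: 925.0
  runtime_h: 16.0
  phi: 0.9
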