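# Seven-group sine replication profile: three uncompensated arms, three
# compensated arms (47 ms latency, residual bounded by the measured compensating errors), one
# standstill reference. 4 s period, 44.4 s / 300 cGy delivery, 3x3 cm field,
# penumbra calibrated to the measured standstill 95% isodose area.
seed: 1
standstill: true
dt_s: 0.01
period_s: 4.0
delivery:
  duration_s: 44.4
  dose_cgy: 300
beam:
  field_x_mm: 30
  field_y_mm: 30
  calibrate_area95_cm2: 5.36
grid:
  spacing_mm: 0.25
  extent_mm: 100
gauge:
  volts_per_mm: 0.1
  offset_v: 2.5
  noise_sd_v: 0.005
compensation:
  latency_s: 0.047
  residual_budget_mm:
    10: 0.92
    20: 1.65
    30: 2.75
gamma:
  dose_tol_pct: 3
  dta_mm: 3
arms:
  - {name: sine10_uncomp, signal: sine, displacement_pp: 10, compensated: false}
  - {name: sine20_uncomp, signal: sine, displacement_pp: 20, compensated: false}
  - {name: sine30_uncomp, signal: sine, displacement_pp: 30, compensated: false}
  - {name: sine10_comp, signal: sine, displacement_pp: 10, compensated: true}
  - {name: sine20_comp, signal: sine, displacement_pp: 20, compensated: true}
  - {name: sine30_comp, signal: sine, displacement_pp: 30, compensated: true}
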