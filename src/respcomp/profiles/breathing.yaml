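# Irregular-breathing replication profile: 60 s human-like traces scaled to
# 10/20/30 mm peak-to-peak displacement, otherwise identical to the sine
# profile (first 44.4 s of motion irradiated).
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
    10: 1.14
    20: 1.70
    30: 2.57
gamma:
  dose_tol_pct: 3
  dta_mm: 3
breathing:
  period_sd_s: 0.25
  amplitude_cv: 0.15
  drift_sd_mm: 0.02
  duration_s: 60
arms:
  - {name: resp10_uncomp, signal: breathing, displacement_pp: 10, compensated: false}
  - {name: resp20_uncomp, signal: breathing, displacement_pp: 20, compensated: false}
  - {name: resp30_uncomp, signal: breathing, displacement_pp: 30, compensated: false}
  - {name: resp10_comp, signal: breathing, displacement_pp: 10, compensated: true}
  - {name: resp20_comp, signal: breathing, displacement_pp: 20, compensated: true}
  - {name: resp30_comp, signal: breathing, displacement_pp: 30, compensated: true}
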