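"""Published measurements from the physical compensation-system evaluation.

The hardware study this simulator models reported a small set of printed
measurements — per-patient fluoroscopy displacement means, film isodose
areas, and tracking-error budgets. They serve two roles here: as worked
inputs for the summary formulas (compensation rate, isodose-area
improvement) and as the calibration / noise budgets that anchor the
simulation to the measured system.

All displacements are millimetres, areas cm^2, errors mm.
"""
from __future__ import annotations

#: per-patient fluoroscopy means with compensation running:
#: (target-simulator mean displacement, residual target mean displacement,
#: printed compensation rate %)
HUMAN_STUDY_MEANS = {
    1: (7.67, 1.92, 75.0),
    2: (6.05, 1.60, 73.6),
    3: (21.39, 7.00, 67.3),
    4: (9.50, 2.44, 74.3),
    5: (9.23, 2.25, 75.6),
    6: (23.51, 4.10, 82.5),
    7: (19.90, 3.98, 80.0),
    8: (21.81, 6.05, 72.27),
    9: (22.99, 4.88, 78.79),
    10: (13.45, 3.01, 77.62),
}

#: standstill film 95% / 5% isodose areas
STANDSTILL_AREA95 = 5.36
STANDSTILL_AREA5 = 18.53

#: film 95% isodose areas by sine amplitude (mm): (uncompensated, compensated)
SINE_AREA95 = {5: (3.78, 4.60), 10: (1.87, 4.303), 15: (0.0, 4.12)}
SINE_AREA5 = {5: (18.93, 17.39), 10: (20.99, 17.54), 15: (23.67, 17.40)}

#: film 95% isodose areas by breathing displacement (mm): (uncompensated, compensated)
BREATHING_AREA95 = {10: (4.06, 5.03), 20: (2.30, 4.57), 30: (0.17, 4.80)}
BREATHING_AREA5 = {10: (18.44, 19.03), 20: (23.00, 18.21), 30: (24.58, 19.18)}

#: measured whole-chain compensating error (mean tracking error, mm) by
#: sine amplitude — used as the simulator's residual-motion noise budget
SINE_COMPENSATING_ERROR = {5: 0.92, 10: 1.65, 15: 2.75}
BREATHING_COMPENSATING_ERROR = {10: 1.14, 20: 1.70, 30: 2.57}

#: measured gamma 3%/3mm passing rates (%) without compensation, by amplitude
#: or displacement; with compensation every case passed at 100%
SINE_GAMMA_UNCOMP = {5: 100.0, 10: 92.0, 15: 0.0}
BREATHING_GAMMA_UNCOMP = {10: 100.0, 20: 84.0, 30: 39.6}

#: control-chain latency, seconds
MEASURED_LATENCY_S = 0.047
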