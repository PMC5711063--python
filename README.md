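# respcomp

In-silico evaluation of a couch-based respiratory motion compensation
system for radiotherapy.

During irradiation of thoracic and abdominal tumours, breathing moves
the target mostly along the superior–inferior (SI) axis, smearing the
delivered dose and forcing larger treatment fields. A compensating couch
counters this by tracking a breathing surrogate (a strain-gauge voltage
from the abdomen, calibrated under fluoroscopy) and moving *opposite* to
the target, so that the tumour stays fixed in the beam frame; what the
film — and the tumour — still experiences is the residual motion
`r(t) = x_target(t) + x_couch(t)`. This package simulates that whole
chain and quantifies the dosimetric benefit, for medical-physics
researchers studying intrafraction motion management.

## Model

* **Motion.** Sinusoidal couch motion `x(t) = A sin(2πt/T)` (T = 4 s,
  A = 5/10/15 mm, i.e. 10/20/30 mm peak-to-peak) or irregular
  raised-cosine breathing with seeded period/amplitude jitter, rescaled
  to an exact peak-to-peak displacement.
* **Surrogate and calibration.** Gauge voltage `v = k·x + v₀ + ε`;
  least-squares gain/shift recovers displacement. The fluoroscopy
  geometry follows similar triangles: motion `b` at distance `a` from
  the source projects to `f = b·e/a` on the imaging plane at distance
  `e`, and a target and reference rod sharing one projected image obey
  `d/b = c/a`.
* **Compensation.** The couch tracks the inverted command with the
  measured 47 ms control latency; a lagged inverted sinusoid leaves a
  residual of amplitude `2A sin(πL/T)` (≈1.107 mm at A = 15 mm).
  Actuator noise is solved so that the residual stays within the
  system's measured compensating-error budget.
* **Dose.** A separable 3×3 cm beam with error-function penumbrae,
  `P(u) = ½[erf((u+w/2)/σ√2) − erf((u−w/2)/σ√2)]`, σ calibrated so the
  standstill 95 % isodose area equals the measured 5.36 cm²; a film
  riding the residual motion accumulates
  `D(x,y) = ρ Σᵢ P_x(x − r(tᵢ)) P_y(y) Δt` over the 44.4 s / 300 cGy
  delivery (11.1 breathing cycles).
* **Metrics.** Isodose areas thresholded against the standstill maximum;
  area improvement `100·(A_comp − A_uncomp)/A_standstill`; mean in-field
  dose; global gamma 3 %/3 mm within the field; per-breath compensation
  rate `100·(1 − residual/target)`.

## Worked example

```python
>>> import respcomp as rc
>>> rc.compensation_rate(7.67, 1.92)   # fluoroscopy means, patient 1
74.96740547588005                      # prints as 75.0 %
>>> rc.improvement(4.12, 0.0, 5.36)    # 95% areas, 30 mm sine films
76.86567164179104                      # 76.9 % of the standstill area regained
```

Running the seven-group sine experiment end to end:

```sh
respcomp run -c paper.yaml -o results/experiment_sine
```

prints (abridged):

```
          arm  area95_cm2  area5_cm2  mean_field_dose_pct  gamma_pass_pct
   standstill        5.36      13.14               100.00          100.00
sine10_uncomp        3.94      15.10                93.61           94.65
sine20_uncomp        1.85      18.06                83.02           48.05
sine30_uncomp        0.00      21.16                72.06           13.05
  sine10_comp        5.36      13.15                99.94          100.00
  sine20_comp        5.25      13.26                99.76          100.00
  sine30_comp        5.23      13.32                99.43          100.00
```

Uncompensated motion erodes the high-dose (95 %) region — completely at
30 mm displacement — and spills dose outside the field (growing 5 %
area), while every compensated arm stays within 3 %/3 mm of the
standstill film everywhere in the field. The numbered scripts under
`analysis/` run the same pipeline stage by stage (signals, calibration,
kinematics, sine and breathing film experiments, combined summary) and
write their tables under `results/`.

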