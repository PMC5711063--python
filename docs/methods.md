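# Methods

This note records the models, parameter choices and numerical decisions
behind `respcomp`, and what the simulations can and cannot say about the
physical system they emulate.

## Motion model

The target (tumour/diaphragm surrogate) moves along the SI axis only —
the compensating couch the package models compensates a single axis, and
AP/LR excursions (~20 % of SI) are out of scope. Two waveform families
are provided:

* **Sine**: `x(t) = A sin(2πt/T + φ)` with T = 4 s and A = 5/10/15 mm
  (10/20/30 mm peak-to-peak couch displacement). These are the
  controlled film-experiment inputs.
* **Irregular breathing**: concatenated raised-cosine cycles
  `a_k·(1 − cos 2πτ/P_k)/2`, anchored at end-exhale, with per-cycle
  period `P_k ~ N(4 s, 0.25 s)` and amplitude factor `~ N(1, 0.15)`,
  plus a Gaussian random-walk baseline (step sd 0.02 mm per 10 ms
  sample), 60 s long. No waveform of the recorded patients was ever
  published; the raised cosine is the simplest shape with distinct
  inhale/exhale and an end-exhale rest, and the jitter magnitudes are
  chosen as a moderate, regular breather. The finished trace is affinely
  rescaled so the global peak-to-peak displacement is *exactly* the
  nominal 10/20/30 mm — the displacement labels are literal, which makes
  cross-arm comparisons exact rather than approximate.

Sampling is 100 Hz (dt = 0.01 s) throughout: fine enough that the 47 ms
control latency is representable as a fractional-sample interpolation
shift, and that time-stepped dose accumulation resolves the motion.

A breathing period outside 2.9–5.6 s warns (physiological range) but is
not rejected.

## Surrogate and calibration

The strain gauge is an affine transducer, `v = k·x + v₀ + ε`,
`ε ~ N(0, σ_v)` (defaults 0.1 V/mm, 2.5 V offset, 5 mV noise ≈ 0.05 mm).
Calibration is ordinary least squares of target displacement on
surrogate voltage; the physical procedure (manual gain/offset tuning
under fluoroscopy until rod and target displacements coincide) has no
algorithmic description, and OLS is its natural idealisation. The shift
term aligns positions only; it never enters the compensation velocity.

The fluoroscopy projection model is exact similar-triangle geometry for
small in-plane translations: `f = b·e/a`, no divergence correction
across the displacement extent, no image-intensifier distortion. The
rod-to-target ratio `d/b = c/a` follows from two objects sharing one
projected excursion. Distances `a, c, e` are configuration values with
no claimed fidelity — the physical setup never published them.

## Compensation loop

`couch(t) = −(1+g)·command(t − L) + noise`, with latency L = 47 ms (the
measured delay of the gauge→amplifier→software→motor chain), optional
multiplicative gain error g, optional per-sample Gaussian actuator
noise, and an optional per-step speed clamp. No predictive filtering of
any kind: the couch tracks a stale command, which is exactly what makes
the residual of a sinusoid `2A sin(πL/T)` — 0.37/0.74/1.11 mm at
A = 5/10/15 mm. The closed form doubles as an analytic oracle in the
tests (agreement < 0.1 %).

**Residual-error budget.** The physical system's "compensating error"
was measured at 0.92/1.65/2.75 mm for the three sine amplitudes, without
a stated statistic. The runner solves the actuator-noise sd (Brent root
find on a fixed unit-normal draw, so arms stay seed-deterministic) so
that the simulated residual matches this budget. The budget statistic is
`max|residual|` by default, with `mae` and `rms` available. The
max-statistic reading is the only one consistent with the published
films: the dose blur depends only on the residual's marginal position
distribution, and a residual with *mean* |r| = 2.75 mm (marginal sd
≈ 3.4 mm) would blur the penumbra far more than the measured compensated
95 % area (4.12 cm², implying an effective blur sd ≈ 1.8 mm) or the
measured 100 % gamma pass allow. Treating the numbers as worst-case
tracking bounds reproduces both.

## Kinematic statistics

Position and compensating errors are mean absolute deviations by
default (rms/max by flag) — the physical study never defined them.
Breaths are segmented at end-exhale minima: local minima of the trace
separated by at least half the dominant period, the dominant period
taken from the autocorrelation peak, deeper minima winning ties. The
rule is deterministic; an independent depth-first scan reproduces it in
the tests. The compensation rate `100·(1 − residual/target)` is applied
to per-cycle mean displacements; applied to the published per-patient
fluoroscopy means it reproduces 9 of 10 printed rates to one decimal
(the remaining one differs by 0.1 — 82.6 vs 82.5 — presumably a
different averaging order upstream of the printed means).

## Beam and film model

The static field is separable,
`D(x,y) = D₀·P_x(x)·P_y(y)`, with an error-function edge profile
normalised to 1 at the centre. No depth dose, scatter, or film response
curve is modelled. The single shape parameter σ (penumbra width) is
*calibrated*: bisection (Brent) until the standstill 95 % isodose area
matches the measured 5.36 cm², giving σ ≈ 2.05 mm at the default grid.
This absorbs the unknown film/densitometry chain into one observable.
The price is that only that observable is matched: the calibrated
standstill 5 % area is 13.1 cm², not the measured 18.53 cm² — an erf
penumbra has no tail heavy enough to produce both printed areas, so the
low-isodose structure of the real films (scatter, glare, scanner
background) is *not* reproduced, and 5 %-area results are comparative
only. The pixel-counted area is quantised (the symmetric contour crosses
up to 8 pixels at once), so the calibration tolerance is
max(0.01 cm², 8 px).

The delivery is 44.4 s for 300 cGy, i.e. dose rate 300/44.4 cGy/s; the
nominal machine setting of 515 MU/min printed alongside is numerically
inconsistent with that pair and is ignored in favour of the time/dose
pair. The film rides the residual motion; dose at film coordinate x
integrates the static profile at `x − r(t)` with left-endpoint steps at
the trace dt (4440 steps per delivery). For whole periods of sinusoidal
motion this converges to convolution with the arcsine density
`1/(π√(A²−u²))`; a Gauss–Chebyshev quadrature of that integral — a
completely different discretisation — agrees with the time-stepped map
to < 0.5 % of the maximum dose, and total dose is conserved under motion
to < 0.1 % on the default grid (margin > max|r| + 5σ).

Grid default: 0.25 mm pixels over 100×100 mm — about 12× finer than the
3 mm DTA, wide enough for 30 mm motion plus penumbra. Grid, film-scan
axis convention (0 at couch side, film centre at 40 mm, field at
25–55 mm) and spacing are configuration, not fidelity claims; the real
films' digitisation is unknown.

## Dosimetric metrics

All arms of one experiment are normalised to the *standstill* film's
maximum: isodose thresholds, the gamma dose criterion, and the mean
in-field dose all reference the standstill state. (Referencing each
film's own maximum would make a fully smeared film's 95 % area
nonzero by construction.) The area-improvement convention is
`100·(A_comp − A_uncomp)/A_standstill`, the only formula that reproduces
the published improvement endpoints from the published area triples. The
published 5 %-area "reduction" percentages cannot be reproduced from the
published areas by this or any other single convention tried; the 5 %
improvement is therefore reported under the same convention as the 95 %
one and not compared.

Gamma is the global-normalisation Low index: for each reference point,
the minimum over evaluated positions within a 9 mm search disc
(bilinear interpolation on a 0.3 mm lattice, nearer offsets first with
a running bound) of `√(d²/dta² + ΔD²/(3 % of ref max)²)`; a point passes
at γ ≤ 1 (with a 1e-9 tie guard so an exact 3 % scaling passes at the
boundary). Evaluation is restricted to the nominal 3×3 cm field,
matching how the physical films were analysed; no low-dose cutoff is
applied. On smooth dose-map-like fields the lattice search agrees with
an exhaustive half-step brute-force search within 0.05 in γ; on fields
with pixel-scale structure the lattice discretisation error grows with
the local dose gradient, as for any sampled gamma implementation.

## What the simulation does and does not reproduce

With the penumbra calibrated to the single standstill observable, the
pipeline reproduces the *endpoints and orderings* of the film study:
the uncompensated 30 mm film's 95 % area collapses to exactly 0 cm²,
uncompensated gamma pass rates and 95 % areas fall strictly with
amplitude, 5 % areas grow, and every compensated arm (residual bounded
by the measured compensating errors) passes 3 %/3 mm at 100 %.
Intermediate values (e.g. the 92 % pass at 20 mm displacement) depend on
the unpublished film profile and patient waveforms and are reproduced
only in ordering.

One endpoint is structurally out of reach: the published in-field gamma
pass of the uncompensated 30 mm film is 0 %, while the simulation gives
≈ 13 %. A blurred profile is lower than the static one mid-field and
higher outside, so the two must cross, and the crossing contour sits
just inside the ±15 mm field boundary; every reference point within
dose-tolerance or 3 mm DTA of that contour passes, a ~1–1.5 mm frame of
the evaluation square. No parameter of the uncompensated arm (which has
none free) removes this band; 0 % would require the real films to
differ near the field edge in a way the erf/arcsine model does not
capture (film registration, scanner response, or an analysis region
smaller than the nominal field).

The synthetic breathing generator emulates displacement scale, cycle
irregularity and drift, not patient-specific waveforms, cough/apnea
events, baseline shifts between sessions, or hysteresis between
surrogate and target — so passing tests demonstrate the pipeline's
internal consistency and its agreement with the published summary
measurements, not fidelity to any individual patient.

## Problem sizes and determinism

Default experiment: 401×401 grid, 4440 time steps per arm, gamma over
121×121 in-field reference points × ~2800 search offsets; a full
seven-group run takes a few seconds on one CPU. All randomness
(breathing jitter, gauge noise, actuator noise) derives from the single
experiment seed via independent spawned streams, and a fixed seed gives
byte-identical summary output.
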