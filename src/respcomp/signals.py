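"""Respiratory trace generation and strain-gauge transduction.

This module produces the one-dimensional superior-inferior (SI) motion
signals that drive the rest of the pipeline:

* :func:`gen_sine` — the regular "couch" motion used in the film
  experiments (4 s period, 5/10/15 mm amplitude, i.e. 10/20/30 mm
  peak-to-peak displacement);
* :func:`gen_breathing` — an irregular human-like breathing trace built
  from raised-cosine cycles with seeded period/amplitude jitter and a
  random-walk baseline drift, rescaled so the global peak-to-peak
  displacement is exact;
* :func:`transduce` — the strain-gauge surrogate: an affine map from
  abdominal displacement to bridge voltage plus Gaussian sensor noise.

All traces are uniformly sampled; the default 100 Hz sampling is fine
enough to represent the 47 ms control latency as a fractional-sample
shift.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import KindMismatchError, ParameterError, TraceFormatError

DISPLACEMENT = "displacement"
VOLTAGE = "voltage"

#: default sampling interval, seconds (100 Hz)
DEFAULT_DT = 0.01

#: physiological breathing-period range, seconds; values outside warn
PHYSIO_PERIOD_RANGE = (2.9, 5.6)


@dataclass(frozen=True, eq=False)
class Trace:
    """A uniformly sampled 1-D signal.

    Parameters
    ----------
    t0 : float
        Time of the first sample, seconds.
    dt : float
        Sampling interval, seconds; must be positive.
    values : numpy.ndarray
        Sample values — millimetres for ``kind="displacement"``, volts
        for ``kind="voltage"``. At least two finite samples.
    kind : str
        Either ``"displacement"`` or ``"voltage"``.
    """

    t0: float
    dt: float
    values: np.ndarray
    kind: str = DISPLACEMENT

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.dt <= 0:
            raise ParameterError(f"dt must be positive, got {self.dt}")
        if vals.ndim != 1 or vals.size < 2:
            raise ParameterError("a trace needs at least 2 samples in a 1-D array")
        if not np.all(np.isfinite(vals)):
            raise ParameterError("trace values must be finite")
        if self.kind not in (DISPLACEMENT, VOLTAGE):
            raise ParameterError(f"unknown trace kind {self.kind!r}")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Span (n-1)*dt of the trace, seconds."""
        return (self.n - 1) * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)

    @property
    def peak_to_peak(self) -> float:
        return float(self.values.max() - self.values.min())

    def sample(self, t: np.ndarray | float) -> np.ndarray:
        """Linear interpolation, held constant beyond either end."""
        return np.interp(t, self.times, self.values)

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "Trace":
        return Trace(self.t0, self.dt, values, kind or self.kind)


@dataclass(frozen=True)
class BreathingParams:
    """Parameters of the irregular breathing generator.

    ``displacement_pp`` is the exact global peak-to-peak displacement in
    mm (the study uses 10/20/30 mm); ``period_mean``/``period_sd``
    control per-cycle period jitter, ``amplitude_cv`` the per-cycle
    amplitude coefficient of variation, and ``drift_sd`` the per-sample
    step of the random-walk baseline drift.
    """

    displacement_pp: float
    period_mean: float = 4.0
    period_sd: float = 0.25
    amplitude_cv: float = 0.15
    drift_sd: float = 0.02
    duration: float = 60.0
    dt: float = DEFAULT_DT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.displacement_pp <= 0:
            raise ParameterError("displacement_pp must be positive")
        if self.period_mean <= 0 or self.dt <= 0:
            raise ParameterError("period_mean and dt must be positive")
        if self.period_sd < 0 or self.amplitude_cv < 0 or self.drift_sd < 0:
            raise ParameterError("jitter parameters must be non-negative")
        lo, hi = PHYSIO_PERIOD_RANGE
        if not lo <= self.period_mean <= hi:
            warnings.warn(
                f"period_mean={self.period_mean} s lies outside the typical "
                f"breathing-cycle range [{lo}, {hi}] s",
                stacklevel=3,
            )


@dataclass(frozen=True)
class GaugeModel:
    """Strain-gauge transducer: voltage = volts_per_mm * x + offset_v + noise."""

    volts_per_mm: float = 0.1
    offset_v: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.volts_per_mm == 0:
            raise ParameterError("volts_per_mm must be nonzero")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")


def gen_sine(
    amplitude: float,
    period: float,
    duration: float,
    dt: float = DEFAULT_DT,
    phase: float = 0.0,
    t0: float = 0.0,
) -> Trace:
    """Sinusoidal SI displacement, ``x(t) = A sin(2*pi*t/period + phase)``.

    An amplitude of ``A`` mm gives a peak-to-peak couch displacement of
    ``2A`` mm once the trace spans at least one period.
    """
    if period <= 0 or dt <= 0:
        raise ParameterError("period and dt must be positive")
    if amplitude < 0:
        raise ParameterError("amplitude must be non-negative")
    if duration < dt:
        raise ParameterError("duration must cover at least one sample interval")
    n = int(round(duration / dt)) + 1
    t = t0 + dt * np.arange(n)
    values = amplitude * np.sin(2.0 * np.pi * t / period + phase)
    return Trace(t0, dt, values, DISPLACEMENT)


def gen_breathing(params: BreathingParams) -> Trace:
    """Irregular breathing trace with exact peak-to-peak displacement.

    Cycles are raised-cosine inhale/exhale bumps anchored at end-exhale;
    per-cycle period ~ N(period_mean, period_sd), per-cycle amplitude
    ~ N(1, amplitude_cv) * displacement_pp / 2, plus a Gaussian
    random-walk baseline. The finished trace is affinely rescaled so the
    global peak-to-peak displacement equals ``displacement_pp`` exactly
    and is centred on zero. Fully reproducible from ``seed``.
    """
    p = params
    if p.duration < p.period_mean:
        raise ParameterError(
            f"duration {p.duration} s is shorter than one mean cycle ({p.period_mean} s)"
        )
    rng = np.random.default_rng(p.seed)
    n = int(round(p.duration / p.dt)) + 1
    t = p.dt * np.arange(n)

    values = np.empty(n)
    start = 0.0
    i0 = 0
    half_pp = p.displacement_pp / 2.0
    while i0 < n:
        period = rng.normal(p.period_mean, p.period_sd)
        period = max(period, 0.25 * p.period_mean)  # keep cycles physical
        amp = half_pp * max(rng.normal(1.0, p.amplitude_cv), 0.05)
        i1 = min(n, int(np.ceil((start + period) / p.dt)))
        phase = (t[i0:i1] - start) / period
        values[i0:i1] = amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
        start += period
        i0 = i1

    if p.drift_sd > 0:
        values += np.cumsum(rng.normal(0.0, p.drift_sd, n))

    span = values.max() - values.min()
    values = (values - values.min()) / span * p.displacement_pp - half_pp
    return Trace(0.0, p.dt, values, DISPLACEMENT)


def transduce(disp: Trace, gm: GaugeModel) -> Trace:
    """Map a displacement trace through the strain-gauge model to voltage."""
    if disp.kind != DISPLACEMENT:
        raise KindMismatchError("transduce expects a displacement trace")
    rng = np.random.default_rng(gm.seed)
    noise = rng.normal(0.0, gm.noise_sd, disp.n) if gm.noise_sd > 0 else 0.0
    v = gm.volts_per_mm * disp.values + gm.offset_v + noise
    return Trace(disp.t0, disp.dt, v, VOLTAGE)


def untransduce(volt: Trace, gm: GaugeModel) -> Trace:
    """Invert the noiseless affine part of the gauge model."""
    if volt.kind != VOLTAGE:
        raise KindMismatchError("untransduce expects a voltage trace")
    x = (volt.values - gm.offset_v) / gm.volts_per_mm
    return Trace(volt.t0, volt.dt, x, DISPLACEMENT)


# ---------------------------------------------------------------------------
# Trace CSV I/O: header "time_s,value", uniform strictly-increasing times.

_HEADER = ("time_s", "value")


def write_trace(trace: Trace, path) -> None:
    df = pd.DataFrame({"time_s": trace.times, "value": trace.values})
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.10g")


def read_trace(path, kind: str = DISPLACEMENT) -> Trace:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise TraceFormatError(f"{path}: empty trace file") from exc
    if tuple(df.columns[:2]) != _HEADER:
        raise TraceFormatError(
            f"{path}: expected header 'time_s,value', got {','.join(map(str, df.columns))}"
        )
    if len(df) < 2:
        raise TraceFormatError(f"{path}: a trace needs at least 2 rows")
    t = df["time_s"].to_numpy(dtype=float)
    steps = np.diff(t)
    # offending sample of step i is data row i+2, i.e. file row i+3 (header = row 1)
    if np.any(steps <= 0):
        row = int(np.argmax(steps <= 0)) + 3
        raise TraceFormatError(f"{path}: time not strictly increasing at row {row}")
    dt = steps[0]
    bad = np.abs(steps - dt) > 1e-6 * dt
    if np.any(bad):
        row = int(np.argmax(bad)) + 3
        raise TraceFormatError(f"{path}: non-uniform sampling at row {row}")
    return Trace(float(t[0]), float(dt), df["value"].to_numpy(dtype=float), kind)
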