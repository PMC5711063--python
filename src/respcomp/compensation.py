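"""Reverse-motion couch compensation and kinematic metrics.

The compensating couch moves opposite to the commanded target motion so
the tumour stays fixed in the beam frame. The physical control chain
(strain gauge -> amplifier -> software -> motor) needs 47 ms, so the
couch always tracks a slightly stale command; for a sinusoidal command
of amplitude ``A`` and period ``T`` the residual motion is itself a
sinusoid of amplitude ``2 A sin(pi * L / T)`` for latency ``L``.

Kinematic summary statistics follow the hardware study's conventions:
position/compensating errors as mean absolute deviations, per-breath
peak-to-peak displacements segmented at end-exhale minima, and the
compensation rate ``100 * (1 - residual / target)`` on mean per-cycle
displacements.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .errors import AlignmentError, DegenerateTraceError, ParameterError
from .signals import DISPLACEMENT, Trace

#: measured latency of the physical control chain, seconds
DEFAULT_LATENCY = 0.047


@dataclass(frozen=True)
class CompensationConfig:
    latency: float = DEFAULT_LATENCY
    gain_error: float = 0.0
    actuator_noise_sd: float = 0.0
    max_speed: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latency < 0:
            raise ParameterError("latency must be non-negative")
        if self.actuator_noise_sd < 0:
            raise ParameterError("actuator_noise_sd must be non-negative")
        if self.max_speed is not None and self.max_speed <= 0:
            raise ParameterError("max_speed must be positive when set")


@dataclass
class KinematicsReport:
    """Kinematic summary of one compensated (or uncompensated) arm."""

    position_error: float
    compensating_error: float
    comp_rate_mean: float
    comp_rate_sd: float
    pearson_r: float
    target_mean_disp: float
    residual_mean_disp: float
    per_cycle: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "position_error_mm": self.position_error,
            "compensating_error_mm": self.compensating_error,
            "comp_rate_mean_pct": self.comp_rate_mean,
            "comp_rate_sd_pct": self.comp_rate_sd,
            "pearson_r": self.pearson_r,
            "target_mean_disp_mm": self.target_mean_disp,
            "residual_mean_disp_mm": self.residual_mean_disp,
        }


def simulate_couch(command: Trace, cfg: CompensationConfig) -> Trace:
    """Latency-delayed inverted tracking of the command.

    ``couch(t) = -(1 + gain_error) * command(t - latency) + noise``, the
    command held at its first value before ``t0 + latency`` (the couch
    has nothing to react to yet). Fractional-sample latency is handled
    by linear interpolation. When ``max_speed`` is set, each per-sample
    move is clipped to ``max_speed * dt``.
    """
    if command.kind != DISPLACEMENT:
        raise ParameterError("simulate_couch expects a displacement command")
    t = command.times
    delayed = np.interp(t - cfg.latency, t, command.values)
    couch = -(1.0 + cfg.gain_error) * delayed
    if cfg.actuator_noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        couch = couch + rng.normal(0.0, cfg.actuator_noise_sd, command.n)
    if cfg.max_speed is not None:
        step = cfg.max_speed * command.dt
        out = np.empty_like(couch)
        out[0] = couch[0]
        for i in range(1, couch.size):
            out[i] = out[i - 1] + np.clip(couch[i] - out[i - 1], -step, step)
        couch = out
    return Trace(command.t0, command.dt, couch, DISPLACEMENT)


def residual(target: Trace, couch: Trace) -> Trace:
    """What the film (and tumour) still does: ``r(t) = target(t) + couch(t)``."""
    if target.n != couch.n or abs(target.dt - couch.dt) > 1e-9 * target.dt:
        raise AlignmentError("target and couch traces must share sampling")
    return Trace(target.t0, target.dt, target.values + couch.values, DISPLACEMENT)


def position_error(command: Trace, achieved: Trace, stat: str = "mae") -> float:
    """Tracking error between commanded and achieved positions.

    ``stat`` selects mean absolute ("mae", default), root-mean-square
    ("rms") or maximum ("max") deviation.
    """
    if command.n != achieved.n:
        raise AlignmentError("command and achieved traces must share sampling")
    d = np.abs(achieved.values - command.values)
    if stat == "mae":
        return float(d.mean())
    if stat == "rms":
        return float(np.sqrt(np.mean(d**2)))
    if stat == "max":
        return float(d.max())
    raise ParameterError(f"unknown statistic {stat!r}")


def compensation_rate(target_mean: float, residual_mean: float) -> float:
    """Percent of target displacement removed: ``100 * (1 - residual/target)``."""
    if target_mean <= 0:
        raise ParameterError("target mean displacement must be positive")
    if residual_mean < 0:
        raise ParameterError("residual mean displacement must be non-negative")
    return 100.0 * (1.0 - residual_mean / target_mean)


def dominant_period(trace: Trace) -> float:
    """Dominant breathing period from the autocorrelation peak, seconds."""
    x = trace.values - trace.values.mean()
    if np.ptp(x) == 0:
        raise DegenerateTraceError("constant trace has no breathing cycle")
    ac = sp_signal.correlate(x, x, mode="full")[x.size - 1 :]
    # first local maximum past the zero-lag peak
    peaks, _ = sp_signal.find_peaks(ac)
    if peaks.size == 0:
        raise DegenerateTraceError("no autocorrelation peak; cannot find a cycle")
    lag = peaks[np.argmax(ac[peaks])]
    return float(lag * trace.dt)


def cycle_minima(trace: Trace) -> np.ndarray:
    """Indices of end-exhale minima separated by >= half the dominant period."""
    period = dominant_period(trace)
    dist = max(1, int(round(0.5 * period / trace.dt)))
    minima, _ = sp_signal.find_peaks(-trace.values, distance=dist)
    if minima.size < 2:
        raise DegenerateTraceError("fewer than two end-exhale minima detected")
    return minima


def cycle_displacements(trace: Trace, minima: np.ndarray | None = None) -> np.ndarray:
    """Per-cycle peak-to-peak displacement (mm), one value per breath.

    Cycles are the intervals between successive end-exhale minima; a
    precomputed ``minima`` array lets the caller impose one segmentation
    on several traces (target and residual of the same arm).
    """
    if minima is None:
        minima = cycle_minima(trace)
    out = []
    for lo, hi in zip(minima[:-1], minima[1:]):
        seg = trace.values[lo : hi + 1]
        out.append(float(seg.max() - seg.min()))
    return np.asarray(out)


def pearson(x: Trace, y: Trace) -> float:
    """Pearson product-moment correlation of two equally sampled traces."""
    if x.n != y.n:
        raise AlignmentError("traces must share length")
    if x.n < 3:
        raise ParameterError("need at least 3 samples for a correlation")
    if np.ptp(x.values) == 0 or np.ptp(y.values) == 0:
        raise DegenerateTraceError("zero-variance trace in correlation")
    return float(sp_stats.pearsonr(x.values, y.values)[0])


def kinematics_report(
    target: Trace,
    couch: Trace,
    command: Trace | None = None,
) -> KinematicsReport:
    """Full kinematic summary of one arm.

    ``target`` is the simulator motion, ``couch`` the achieved
    compensating motion, ``command`` the (calibrated) signal the couch
    was asked to track — defaults to the target itself. The cycle
    segmentation of the target is reused for the residual so per-cycle
    rates compare like with like.
    """
    cmd = command if command is not None else target
    res = residual(target, couch)
    minima = cycle_minima(target)
    target_pp = cycle_displacements(target, minima)
    residual_pp = cycle_displacements(res, minima)
    rates = 100.0 * (1.0 - residual_pp / target_pp)
    per_cycle = pd.DataFrame(
        {
            "cycle": np.arange(1, target_pp.size + 1),
            "target_pp_mm": target_pp,
            "residual_pp_mm": residual_pp,
            "rate_pct": rates,
        }
    )
    inverted = Trace(couch.t0, couch.dt, -couch.values, DISPLACEMENT)
    # an uncompensated arm has a constant (zero) couch: correlation is undefined
    r = pearson(target, inverted) if np.ptp(inverted.values) > 0 else float("nan")
    return KinematicsReport(
        position_error=position_error(cmd, inverted),
        compensating_error=float(np.abs(res.values).mean()),
        comp_rate_mean=float(rates.mean()),
        comp_rate_sd=float(rates.std(ddof=1)) if rates.size > 1 else 0.0,
        pearson_r=r,
        target_mean_disp=float(target_pp.mean()),
        residual_mean_disp=float(residual_pp.mean()),
        per_cycle=per_cycle,
    )


def lagged_sine_residual_amplitude(amplitude: float, period: float, latency: float) -> float:
    """Closed-form residual amplitude ``2 A sin(pi L / T)`` of a lagged inverted sinusoid."""
    return 2.0 * amplitude * np.sin(np.pi * latency / period)
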