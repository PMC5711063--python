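"""Fluoroscopy similar-triangle projection model and surrogate calibration.

A C-arm source projects both the internal target (diaphragm, clip) and
the external L-shaped reference rod onto one imaging plane. For an
object at distance ``dist`` from the source, an in-plane motion ``b``
appears on the imaging plane (distance ``e`` from the source) magnified
by ``e / dist``. Because the target (at distance ``a``) and the rod (at
distance ``c``) share the projected excursion ``f``, their true motions
obey ``d / b = c / a`` — this ratio converts rod motion to target motion
without knowing either absolutely.

The voltage-to-displacement calibration that the physical system does by
manually tuning gain and offset under fluoroscopy is implemented here as
an ordinary least-squares affine fit.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, DegenerateFitError, GeometryError
from .signals import Trace


@dataclass(frozen=True)
class GeometrySetup:
    """Distances (mm) from the C-arm source: target ``a``, rod ``c``, imaging plane ``e``."""

    a: float
    c: float
    e: float

    def __post_init__(self) -> None:
        if not (0 < self.a <= self.e):
            raise GeometryError(f"need 0 < a <= e, got a={self.a}, e={self.e}")
        if not (0 < self.c <= self.e):
            raise GeometryError(f"need 0 < c <= e, got c={self.c}, e={self.e}")


@dataclass(frozen=True)
class AffineCal:
    """Result of the surrogate-to-target affine calibration.

    ``gain`` is mm per surrogate unit (mm/V for a voltage surrogate),
    ``shift`` the alignment offset in mm, ``residual_rms`` the RMS of
    the fit residuals in mm.
    """

    gain: float
    shift: float
    residual_rms: float

    def apply(self, surrogate: Trace) -> Trace:
        """Map a surrogate trace to calibrated displacement (mm)."""
        return Trace(
            surrogate.t0,
            surrogate.dt,
            self.gain * surrogate.values + self.shift,
            "displacement",
        )


def _check_dist(dist: float, geo: GeometrySetup) -> None:
    if not (0 < dist <= geo.e):
        raise GeometryError(
            f"object distance {dist} mm must lie in (0, e={geo.e}] mm"
        )


def project(true_disp: float, dist: float, geo: GeometrySetup) -> float:
    """Project an in-plane motion onto the imaging plane: ``f = x * e / dist``."""
    _check_dist(dist, geo)
    return true_disp * geo.e / dist


def backproject(f: float, dist: float, geo: GeometrySetup) -> float:
    """Recover true motion from its projection: ``x = f * dist / e``."""
    _check_dist(dist, geo)
    return f * dist / geo.e


def rod_to_target_ratio(geo: GeometrySetup) -> float:
    """Ratio ``d/b = c/a`` of rod motion to target motion for a shared projection."""
    return geo.c / geo.a


def fit_affine(surrogate: Trace, target: Trace) -> AffineCal:
    """Least-squares gain/shift mapping the surrogate onto the target.

    Minimises ``sum((gain * s_i + shift - x_i)**2)`` via the normal
    equations (numpy lstsq). Raises :class:`DegenerateFitError` when the
    surrogate is constant.
    """
    if surrogate.n != target.n:
        raise AlignmentError(
            f"length mismatch: surrogate has {surrogate.n} samples, target {target.n}"
        )
    if abs(surrogate.dt - target.dt) > 1e-9 * target.dt:
        raise AlignmentError("surrogate and target must share the sampling interval")
    s = surrogate.values
    x = target.values
    if np.ptp(s) == 0:
        raise DegenerateFitError("surrogate has zero variance; gain is unidentifiable")
    design = np.column_stack([s, np.ones_like(s)])
    (gain, shift), *_ = np.linalg.lstsq(design, x, rcond=None)
    resid = design @ np.array([gain, shift]) - x
    return AffineCal(float(gain), float(shift), float(np.sqrt(np.mean(resid**2))))
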