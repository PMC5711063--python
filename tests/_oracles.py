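"""Independent oracles used by the test suite.

Each helper re-derives a quantity by a different route than the library
(exhaustive search, quadrature, closed form), so agreement is evidence
rather than tautology.
"""
from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates


def brute_force_gamma(ev_dose, ref_dose, spacing, dose_tol, dta, search_radius, step):
    """Exhaustive fine-lattice gamma over the whole grid (no shortcuts)."""
    ny, nx = ref_dose.shape
    g2 = np.full((ny, nx), np.inf)
    crit = dose_tol / 100.0 * ref_dose.max()
    noff = int(np.floor(search_radius / step))
    jj, ii = np.mgrid[0:ny, 0:nx]
    for dy in np.arange(-noff, noff + 1) * step / spacing:
        for dx in np.arange(-noff, noff + 1) * step / spacing:
            d2mm = (dx**2 + dy**2) * spacing**2
            if d2mm > search_radius**2 + 1e-12:
                continue
            coords = np.vstack([(jj + dy).ravel(), (ii + dx).ravel()])
            de = map_coordinates(ev_dose, coords, order=1, mode="nearest").reshape(ny, nx)
            g2 = np.minimum(g2, d2mm / dta**2 + ((de - ref_dose) / crit) ** 2)
    return np.sqrt(g2)


def arcsine_blur(profile_fn, amplitude, x, m=4000):
    """Convolution of a 1-D profile with the arcsine position density.

    Over whole periods, a sinusoid of amplitude A occupies position u with
    density 1/(pi*sqrt(A^2-u^2)); Gauss-Chebyshev quadrature turns the
    singular integral into an average over cosine-spaced nodes, an
    entirely different discretisation than time stepping.
    """
    k = np.arange(1, m + 1)
    nodes = amplitude * np.cos((2 * k - 1) * np.pi / (2 * m))
    return np.mean([profile_fn(x - u) for u in nodes], axis=0)


def scan_cycle_displacements(values, min_sep):
    """Hand-rolled cycle segmentation: depth-first greedy pick of local minima.

    Deepest minima are accepted first; later candidates within ``min_sep``
    samples of an accepted one are dropped — the same deterministic rule
    as the library's peak-based segmentation, coded independently.
    """
    candidates = [
        i
        for i in range(1, len(values) - 1)
        if values[i] <= values[i - 1] and values[i] <= values[i + 1]
    ]
    kept: list[int] = []
    for i in sorted(candidates, key=lambda i: values[i]):
        if all(abs(i - j) >= min_sep for j in kept):
            kept.append(i)
    kept.sort()
    out = []
    for lo, hi in zip(kept[:-1], kept[1:]):
        seg = values[lo : hi + 1]
        out.append(seg.max() - seg.min())
    return np.asarray(out), np.asarray(kept)


def dominant_period_fft(values, dt):
    """Dominant period via the discrete power spectrum (excludes DC)."""
    v = values - values.mean()
    power = np.abs(np.fft.rfft(v)) ** 2
    freqs = np.fft.rfftfreq(v.size, dt)
    k = 1 + int(np.argmax(power[1:]))
    return 1.0 / freqs[k]


def affine_normal_equations(s, x):
    """Closed-form least-squares gain/shift from covariance identities."""
    gain = np.cov(s, x, bias=True)[0, 1] / np.var(s)
    shift = x.mean() - gain * s.mean()
    return gain, shift
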