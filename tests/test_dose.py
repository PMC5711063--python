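from dataclasses import replace

import numpy as np
import pytest

import respcomp as rc
from _oracles import arcsine_blur
from respcomp.errors import CalibrationError, CoverageError, GridError, ParameterError


class TestStaticDose:
    def test_center_pixel_equals_norm_dose(self, beam, grid_spec):
        g = rc.static_dose(beam, grid_spec)
        assert g.dose[g.ny // 2, g.nx // 2] == pytest.approx(300.0, rel=1e-12)

    def test_hard_edge_limit(self):
        beam = rc.BeamModel(penumbra_sigma=0.01)
        g = rc.static_dose(beam, rc.GridSpec(spacing=0.5))
        x = g.x
        inside = np.abs(x) < 14.0
        outside = np.abs(x) > 16.0
        row = g.dose[g.ny // 2]
        np.testing.assert_allclose(row[inside], 300.0, rtol=1e-9)
        np.testing.assert_allclose(row[outside], 0.0, atol=1e-9)

    def test_half_value_at_field_edge(self):
        # P(+-w/2) -> 0.5 * P(0) in the small-sigma regime (erf identity)
        beam = rc.BeamModel(penumbra_sigma=1.0)
        edge = beam.profile_x(np.array([15.0]))[0]
        assert edge == pytest.approx(0.5, abs=1e-6)

    def test_grid_smaller_than_field_rejected(self, beam):
        with pytest.raises(GridError):
            rc.static_dose(beam, rc.GridSpec(spacing=0.5, extent_x=20.0, extent_y=20.0))


class TestCalibratePenumbra:
    def test_standstill_95_area_matches_target(self, beam, grid_spec):
        g = rc.static_dose(beam, grid_spec)
        area = rc.isodose_area(g, 95.0, g.max)
        assert area == pytest.approx(5.36, abs=0.01)

    def test_area_monotone_decreasing_in_sigma(self, grid_spec):
        areas = []
        for s in (1.0, 2.0, 3.0, 4.0):
            g = rc.static_dose(rc.BeamModel(penumbra_sigma=s), grid_spec)
            areas.append(rc.isodose_area(g, 95.0, g.max))
        assert all(a > b for a, b in zip(areas, areas[1:]))

    def test_unbracketable_target_rejected(self):
        with pytest.raises(CalibrationError):
            rc.calibrate_penumbra(9.1, rc.BeamModel())  # more than the field area at any sigma

    def test_target_outside_field_area_rejected(self):
        with pytest.raises(CalibrationError):
            rc.calibrate_penumbra(10.0, rc.BeamModel())


class TestAccumulate:
    def test_standstill_reproduces_static(self, beam, grid_spec):
        zero = rc.Trace(0, 0.01, np.zeros(4441))
        moving = rc.accumulate(beam, zero, 44.4, grid_spec)
        static = rc.static_dose(beam, grid_spec)
        scale = 44.4 * beam.dose_rate / beam.norm_dose
        np.testing.assert_allclose(moving.dose, static.dose * scale, rtol=1e-9)
        assert scale == pytest.approx(1.0)  # 300 cGy over 44.4 s by construction

    def test_constant_offset_shifts_dose(self, beam):
        spec = rc.GridSpec(spacing=0.5)
        off = rc.Trace(0, 0.01, np.full(1001, 5.0))
        shifted = rc.accumulate(beam, off, 10.0, spec)
        static = rc.accumulate(beam, None, 10.0, spec)
        # dose at x samples the beam at x - 5 mm: shifted by +5 mm along x
        k = int(round(5.0 / spec.spacing))
        np.testing.assert_allclose(
            shifted.dose[:, k:], static.dose[:, :-k], rtol=1e-9
        )

    def test_sine_motion_matches_arcsine_convolution(self, beam, grid_spec):
        # whole periods of sinusoidal motion blur the profile with the
        # arcsine position density; Gauss-Chebyshev quadrature is the oracle
        A = 15.0
        tr = rc.gen_sine(A, 4.0, 40.0, dt=0.01)
        g = rc.accumulate(beam, tr, 40.0, grid_spec)
        row = g.dose[g.ny // 2]
        expected = (
            40.0 * beam.dose_rate * arcsine_blur(beam.profile_x, A, grid_spec.x)
        )
        assert np.max(np.abs(row - expected)) < 0.005 * g.max

    def test_dose_conserved_under_motion(self, beam, grid_spec):
        tr = rc.gen_sine(15.0, 4.0, 44.4, dt=0.01)
        blurred = rc.accumulate(beam, tr, 44.4, grid_spec)
        still = rc.accumulate(beam, None, 44.4, grid_spec)
        assert blurred.dose.sum() == pytest.approx(still.dose.sum(), rel=1e-3)

    def test_linear_in_duration_and_dose_rate(self, beam):
        spec = rc.GridSpec(spacing=1.0)
        tr = rc.gen_sine(5, 4, 8, dt=0.01)
        g1 = rc.accumulate(beam, tr, 4.0, spec)
        g2 = rc.accumulate(beam, tr.with_values(tr.values), 8.0, spec)
        double_rate = replace(beam, dose_rate=2 * beam.dose_rate)
        g3 = rc.accumulate(double_rate, tr, 4.0, spec)
        assert g2.dose.sum() > g1.dose.sum()
        np.testing.assert_allclose(g3.dose, 2 * g1.dose, rtol=1e-12)

    def test_short_trace_rejected(self, beam, grid_spec):
        tr = rc.gen_sine(5, 4, 10, dt=0.01)
        with pytest.raises(CoverageError):
            rc.accumulate(beam, tr, 44.4, grid_spec)

    def test_nonpositive_duration_rejected(self, beam, grid_spec):
        with pytest.raises(ParameterError):
            rc.accumulate(beam, None, 0.0, grid_spec)


class TestProfile:
    def test_standstill_flat_inside_field(self, standstill, beam):
        prof = rc.profile(standstill)
        pos, dose = prof[:, 0], prof[:, 1]
        sigma = beam.penumbra_sigma
        # central flat region: the nominal 25-55 mm field minus the penumbra
        core = (pos > 25 + 3 * sigma) & (pos < 55 - 3 * sigma)
        assert np.all(dose[core] >= 0.95 * standstill.max)

    def test_symmetric_motion_gives_symmetric_profile(self, beam, grid_spec):
        tr = rc.gen_sine(10, 4, 40, dt=0.01)
        g = rc.accumulate(beam, tr, 40.0, grid_spec)
        row = g.dose[g.ny // 2]
        assert np.max(np.abs(row - row[::-1])) < 1e-3 * g.max

    def test_axis_convention(self, standstill):
        prof = rc.profile(standstill)
        # film centre at 40 mm on the scan axis
        assert prof[np.argmax(prof[:, 1]), 0] == pytest.approx(40.0, abs=0.25)
        assert prof[0, 0] == pytest.approx(-10.0)  # 100 mm grid on an 80 mm axis

    def test_constant_offset_shifts_profile(self, beam):
        spec = rc.GridSpec(spacing=0.5)
        off = rc.Trace(0, 0.01, np.full(1001, 4.0))
        moved = rc.profile(rc.accumulate(beam, off, 10.0, spec))
        still = rc.profile(rc.accumulate(beam, None, 10.0, spec))
        k = int(round(4.0 / spec.spacing))
        np.testing.assert_allclose(moved[k:, 1], still[:-k, 1], rtol=1e-9)


class TestGridIO:
    def test_round_trip(self, tmp_path, beam):
        g = rc.static_dose(beam, rc.GridSpec(spacing=1.0))
        rc.write_grid(g, tmp_path / "film.grid")
        back = rc.read_grid(tmp_path / "film.grid")
        assert back.spacing == g.spacing
        np.testing.assert_allclose(back.dose, g.dose, rtol=1e-6)

    def test_shape_mismatch_rejected(self, tmp_path, beam):
        g = rc.static_dose(beam, rc.GridSpec(spacing=1.0))
        rc.write_grid(g, tmp_path / "film.grid")
        # corrupt the sidecar
        import json

        sidecar = json.loads((tmp_path / "film.grid.json").read_text())
        sidecar["nx"] += 1
        (tmp_path / "film.grid.json").write_text(json.dumps(sidecar))
        with pytest.raises(GridError):
            rc.read_grid(tmp_path / "film.grid")
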