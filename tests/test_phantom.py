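"""Phantom generator: waveforms, field assembly, ground truth, simulated TTE."""

import math

import numpy as np
import pytest

from pcflow.phantom import (
    BaseFlow,
    JetSpec,
    PlaneSpec,
    SEVERITY_ORDER,
    WaveformParams,
    default_planes,
    field_flux_ml,
    field_peak_speed_curve,
    ground_truth_summary,
    jet_axis_vector,
    jet_waveform,
    make_subject,
    make_velocity_field,
    simulate_tte,
)


class TestJetWaveform:
    @pytest.mark.parametrize(
        "t, expected",
        [
            (160.0, 1.0),             # mid-systole peak
            (0.0, 0.0),               # onset
            (80.0, math.sin(math.pi / 4)),
            (320.0, 0.0),             # end of systole
            (500.0, 0.0),             # diastole
            (-10.0, 0.0),             # before onset
        ],
    )
    def test_halfsine_values(self, t, expected):
        assert jet_waveform(t, WaveformParams()) == pytest.approx(expected, abs=1e-12)

    def test_vectorised_matches_scalar(self):
        p = WaveformParams(onset_ms=20.0, systole_ms=300.0)
        ts = np.linspace(-50, 900, 97)
        vec = jet_waveform(ts, p)
        assert np.allclose(vec, [jet_waveform(float(t), p) for t in ts])

    def test_regurgitant_diastole_is_negative(self):
        p = WaveformParams(systole_ms=320.0, cycle_ms=800.0,
                           regurgitant_fraction=0.3)
        w = jet_waveform(560.0, p)  # mid-diastole
        assert w == pytest.approx(-0.3, abs=1e-12)

    def test_nonpositive_systole_rejected(self):
        with pytest.raises(ValueError):
            WaveformParams(systole_ms=0.0)


class TestMakeVelocityField:
    def test_aligned_jet_peaks_at_nominal_speed(self, small_plane):
        f = make_velocity_field(small_plane, [JetSpec(peak_speed=300.0)])
        assert f.vz.max() == pytest.approx(300.0, abs=1e-12)
        assert np.abs(f.vx).max() == 0.0
        assert np.abs(f.vy).max() == 0.0

    def test_tilted_jet_projects_by_cosine(self, small_plane):
        f = make_velocity_field(
            small_plane, [JetSpec(peak_speed=200.0, tilt_polar=30.0)]
        )
        assert f.vz.max() == pytest.approx(200.0 * math.cos(math.radians(30)),
                                           rel=1e-12)
        assert f.speed().max() == pytest.approx(200.0, rel=1e-12)

    def test_empty_configuration_gives_zero_field(self, small_plane):
        f = make_velocity_field(small_plane, [], BaseFlow(peak_speed=0.0))
        assert not f.vz.any() and not f.vx.any() and not f.vy.any()

    def test_velocities_vanish_outside_lumen(self, small_plane):
        f = make_velocity_field(
            small_plane,
            [JetSpec(peak_speed=250.0, tilt_polar=20.0, sigma=8.0)],
            BaseFlow(peak_speed=60.0),
        )
        outside = ~f.lumen_mask
        assert not f.vz[:, outside].any()
        assert not f.vx[:, outside].any()

    def test_jet_outside_lumen_names_offender(self, small_plane):
        with pytest.raises(ValueError, match="jet 1"):
            make_velocity_field(
                small_plane,
                [JetSpec(), JetSpec(center_xy=(25.0, 0.0))],
            )

    @pytest.mark.parametrize("tilt", [0.0, 10.0, 20.0, 30.0, 40.0])
    def test_peak_speed_invariant_under_tilt(self, small_plane, tilt):
        """Max pixel speed is tilt-independent; max vz scales as cos(tilt)."""
        f = make_velocity_field(
            small_plane, [JetSpec(peak_speed=300.0, tilt_polar=tilt)]
        )
        assert f.speed().max() == pytest.approx(300.0, rel=0.01)
        assert f.vz.max() == pytest.approx(
            300.0 * math.cos(math.radians(tilt)), rel=0.01
        )

    def test_jet_axis_is_unit(self):
        a = jet_axis_vector(JetSpec(tilt_polar=37.0, tilt_azimuth=122.0))
        assert np.linalg.norm(a) == pytest.approx(1.0, abs=1e-12)


class TestPlaneSpec:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"grid_nx": 8},
            {"pixel_size": 0.0},
            {"n_frames": 4},
            {"frame_dt": -1.0},
        ],
    )
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PlaneSpec(**kwargs)


class TestGroundTruth:
    def test_uniform_flow_stroke_volume(self):
        """Uniform 10 cm/s over 10 cm^2 for 1 s integrates to 100 mL."""
        plane = PlaneSpec(grid_nx=16, grid_ny=16, pixel_size=5.0, n_frames=8,
                          frame_dt=125.0)
        f = make_velocity_field(plane, [], BaseFlow(peak_speed=0.0))
        mask = np.zeros((16, 16), bool)
        mask.flat[:40] = True  # 40 px * 0.25 cm^2 = 10 cm^2
        f.vz[:, mask] = 10.0
        assert field_flux_ml(f, mask) == pytest.approx(100.0, rel=1e-12)

    def test_zero_field_zero_flux(self, small_plane):
        f = make_velocity_field(small_plane, [], BaseFlow(peak_speed=0.0))
        assert field_flux_ml(f) == 0.0

    def test_parabolic_flux_matches_closed_form(self):
        """Poiseuille flux (vp/2)*pi*r^2 per unit time, on a fine grid.

        The analytic spatial integral is compared against the grid Riemann
        sum with the same temporal sampling; agreement within 1%.
        """
        plane = PlaneSpec(grid_nx=128, grid_ny=128, pixel_size=0.5,
                          n_frames=8, frame_dt=40.0)
        vp, radius_mm = 80.0, 15.0
        f = make_velocity_field(plane, [], BaseFlow(peak_speed=vp),
                                lumen_radius=radius_mm)
        w = jet_waveform(plane.frame_times, BaseFlow().waveform)
        area_cm2 = math.pi * (radius_mm / 10.0) ** 2
        analytic = (vp / 2.0) * area_cm2 * float(np.sum(w)) * plane.frame_dt / 1000.0
        assert field_flux_ml(f) == pytest.approx(analytic, rel=0.01)

    def test_effective_orifice_area_consistency(self):
        fields, truth = make_subject("moderate", seed=11, second_jet_prob=0.0)
        best = max(truth.true_peak_speed_per_plane,
                   key=truth.true_peak_speed_per_plane.get)
        t, v = field_peak_speed_curve(fields[best])
        vti = np.trapezoid(v, t / 1000.0)
        assert truth.effective_orifice_area == pytest.approx(
            truth.true_sv_per_plane[best] / vti, rel=1e-12
        )


class TestMakeSubject:
    @pytest.mark.parametrize("severity", SEVERITY_ORDER)
    def test_severity_bands_respected(self, severity):
        _, truth = make_subject(severity, seed=5)
        peak = truth.true_peak_speed
        if severity == "severe":
            assert peak > 400.0
        elif severity == "none":
            assert peak < 200.0
        assert truth.severity_label == severity

    def test_same_seed_bit_identical(self):
        f1, t1 = make_subject("moderate", seed=9)
        f2, t2 = make_subject("moderate", seed=9)
        for k in f1:
            assert np.array_equal(f1[k].vz, f2[k].vz)
            assert np.array_equal(f1[k].vx, f2[k].vx)
        assert t1.true_sv == t2.true_sv

    def test_different_seed_differs(self):
        f1, _ = make_subject("moderate", seed=9)
        f2, _ = make_subject("moderate", seed=10)
        assert not np.array_equal(f1[0].vz, f2[0].vz)

    def test_unknown_severity_rejected(self):
        with pytest.raises(ValueError, match="unknown severity"):
            make_subject("critical", seed=0)

    def test_distal_plane_carries_lower_peak(self):
        _, truth = make_subject("severe", seed=21, second_jet_prob=0.0)
        peaks = truth.true_peak_speed_per_plane
        assert peaks[2] < max(peaks[0], peaks[1])


class TestSimulateTTE:
    def _subject(self, tilt):
        plane = PlaneSpec(grid_nx=48, grid_ny=48, pixel_size=1.95)
        planes = default_planes(plane)
        fields = {
            p.plane_index: make_velocity_field(
                p, [JetSpec(peak_speed=300.0, tilt_polar=tilt)]
            )
            for p in planes if p.plane_index != -1
        }
        truth = ground_truth_summary(fields, lvot_diameter=2.2)
        return fields, truth

    def test_parallel_beam_recovers_truth(self):
        fields, truth = self._subject(0.0)
        m = simulate_tte(fields, truth, [np.array([0.0, 0.0, 1.0])])
        assert m.vpeak == pytest.approx(truth.true_peak_speed / 100.0, rel=1e-12)
        assert m.pg == pytest.approx(4.0 * m.vpeak**2, rel=1e-12)

    def test_misaligned_beam_projects_by_cosine(self):
        fields, truth = self._subject(30.0)
        m = simulate_tte(fields, truth, [np.array([0.0, 0.0, 1.0])])
        assert m.vpeak == pytest.approx(
            truth.true_peak_speed / 100.0 * math.cos(math.radians(30)), rel=1e-6
        )

    def test_best_window_selection(self):
        fields, truth = self._subject(30.0)
        jet_axis = jet_axis_vector(JetSpec(tilt_polar=30.0))
        m = simulate_tte(
            fields, truth, [np.array([0.0, 0.0, 1.0]), jet_axis]
        )
        assert m.vpeak == pytest.approx(truth.true_peak_speed / 100.0, rel=1e-6)

    def test_empty_window_list_rejected(self):
        fields, truth = self._subject(0.0)
        with pytest.raises(ValueError, match="empty"):
            simulate_tte(fields, truth, [])

    def test_non_unit_beam_rejected(self):
        fields, truth = self._subject(0.0)
        with pytest.raises(ValueError, match="unit"):
            simulate_tte(fields, truth, [np.array([0.0, 0.0, 2.0])])
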