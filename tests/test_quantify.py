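"""Hemodynamic quantification: thresholds, curves, gradients, SV, AVA."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pcflow.encoding import VelocityMaps, decode_velocities, encode_four_point
from pcflow.phantom import (
    BaseFlow,
    JetSpec,
    PlaneSpec,
    ground_truth_summary,
    make_velocity_field,
)
from pcflow.quantify import (
    PeakCurve,
    SalvageFailedError,
    ThresholdConfig,
    ava_cine,
    ava_continuity,
    ava_flow,
    bernoulli_gradient,
    lvot_area,
    mean_gradient,
    peak_velocity_curve,
    quantify_subject,
    select_plane,
    speed_map,
    stroke_volume_pc,
    threshold_mask,
    v_mean,
    vti,
)


def _maps_from(field, venc=400.0, noise=0.0, seed=0):
    return decode_velocities(
        encode_four_point(field, venc, noise_sigma=noise, seed=seed),
        detect=False,
    )


def _synthetic_maps(plane, vx=0.0, vy=0.0, vz=0.0, venc=400.0):
    shape = (plane.n_frames, plane.grid_ny, plane.grid_nx)
    return VelocityMaps(
        vx=np.full(shape, vx), vy=np.full(shape, vy), vz=np.full(shape, vz),
        magnitude=np.ones(shape), venc=venc, plane=plane,
    )


class TestSpeedMap:
    def test_pythagorean_triple(self, small_plane):
        m = _synthetic_maps(small_plane, vx=30.0, vy=40.0, vz=120.0)
        assert np.allclose(speed_map(m), 130.0)  # 1.3 m/s in cm/s

    def test_single_component_is_absolute_value(self, small_plane):
        m = _synthetic_maps(small_plane, vz=-75.0)
        assert np.allclose(speed_map(m), 75.0)

    def test_zero_field(self, small_plane):
        assert not speed_map(_synthetic_maps(small_plane)).any()


class TestThresholdMask:
    def test_high_flow_lumen_fully_retained(self, small_plane):
        f = make_velocity_field(small_plane, [], BaseFlow(peak_speed=0.0))
        f.vz[:, f.lumen_mask] = 100.0
        m = _maps_from(f, venc=200.0)
        mask = threshold_mask(m, "3Dir", roi=None)
        assert np.array_equal(mask, f.lumen_mask)

    def test_background_and_stagnant_pixels_rejected(self, small_plane):
        f = make_velocity_field(small_plane, [], BaseFlow(peak_speed=0.0))
        f.vz[:, f.lumen_mask] = 100.0
        yx = tuple(np.argwhere(f.lumen_mask)[0])
        f.vz[:, yx[0], yx[1]] = 0.0  # one stagnant lumen pixel
        mask = threshold_mask(_maps_from(f, venc=200.0), "1Dir")
        assert not mask[~f.lumen_mask].any()
        assert not mask[yx]

    def test_empty_mask_raises(self, small_plane):
        f = make_velocity_field(small_plane, [], BaseFlow(peak_speed=0.0))
        with pytest.raises(ValueError, match="no pixels survive"):
            threshold_mask(_maps_from(f), "3Dir")

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ThresholdConfig(mag_frac=1.5)
        with pytest.raises(ValueError):
            ThresholdConfig(flow_floor_frac=-0.1)


class TestPeakCurveOps:
    def test_aligned_jet_curve_tracks_waveform(self, aligned_jet_field):
        f = aligned_jet_field
        m = _maps_from(f)
        mask = threshold_mask(m, "3Dir", roi=f.lumen_mask)
        curve = peak_velocity_curve(m, mask, "3Dir")
        expected = f.vz.reshape(f.plane.n_frames, -1).max(axis=1)
        assert np.allclose(curve.v, expected, atol=1e-8)

    def test_zero_field_gives_zero_curve(self, small_plane):
        m = _synthetic_maps(small_plane)
        curve = peak_velocity_curve(m, np.ones((32, 32), bool), "3Dir")
        assert not curve.v.any()

    def test_tilted_jet_mode_split(self, small_plane):
        f = make_velocity_field(
            small_plane, [JetSpec(peak_speed=300.0, tilt_polar=30.0)]
        )
        m = _maps_from(f)
        mask = f.lumen_mask
        v1 = peak_velocity_curve(m, mask, "1Dir").v.max()
        v3 = peak_velocity_curve(m, mask, "3Dir").v.max()
        assert v1 == pytest.approx(300.0 * math.cos(math.radians(30)), rel=1e-6)
        assert v3 == pytest.approx(300.0, rel=1e-6)

    def test_select_plane(self):
        t = np.arange(8.0)
        mk = lambda peak: PeakCurve(t=t, v=np.full(8, peak), plane_index=0)
        assert select_plane([mk(300.0), mk(320.0), mk(290.0)]) == 1
        assert select_plane([mk(300.0), mk(300.0), mk(300.0)]) == 0
        assert select_plane([mk(250.0)]) == 0
        with pytest.raises(ValueError):
            select_plane([])


class TestVelocityStatistics:
    def test_constant_curve_mean(self):
        c = PeakCurve(t=np.arange(10.0) * 40, v=np.full(10, 200.0), plane_index=0)
        assert v_mean(c, "ejection") == pytest.approx(2.0)
        assert v_mean(c, "full_cycle") == pytest.approx(2.0)

    def test_dense_halfsine_mean_is_two_over_pi(self, dense_halfsine_curve):
        vp = dense_halfsine_curve.v.max() / 100.0
        assert v_mean(dense_halfsine_curve, "ejection") == pytest.approx(
            (2.0 / math.pi) * vp, rel=0.01
        )

    def test_zero_curve_mean(self):
        c = PeakCurve(t=np.arange(8.0), v=np.zeros(8), plane_index=0)
        assert v_mean(c) == 0.0

    @pytest.mark.parametrize("v, pg", [(3.0, 36.0), (1.0, 4.0), (0.0, 0.0)])
    def test_bernoulli(self, v, pg):
        assert bernoulli_gradient(v) == pytest.approx(pg)

    def test_bernoulli_rejects_negative(self):
        with pytest.raises(ValueError):
            bernoulli_gradient(-1.0)

    def test_dense_halfsine_mean_gradient(self, dense_halfsine_curve):
        """Time-average of 4 v^2 over the ejection window: 2 Vp^2 (sin^2
        averages to 1/2)."""
        vp = dense_halfsine_curve.v.max() / 100.0
        assert mean_gradient(dense_halfsine_curve) == pytest.approx(
            2.0 * vp**2, rel=0.01
        )

    def test_mg_below_pg(self, dense_halfsine_curve):
        vp = dense_halfsine_curve.v.max() / 100.0
        assert mean_gradient(dense_halfsine_curve) <= bernoulli_gradient(vp)


class TestVTI:
    def test_constant_velocity(self):
        t = np.linspace(0.0, 300.0, 61)
        c = PeakCurve(t=t, v=np.full_like(t, 100.0), plane_index=0)
        assert vti(c) == pytest.approx(30.0)

    def test_dense_halfsine_closed_form(self, dense_halfsine_curve):
        # (2/pi) * 400 cm/s * 0.32 s
        assert vti(dense_halfsine_curve) == pytest.approx(
            (2.0 / math.pi) * 400.0 * 0.32, rel=0.01
        )

    def test_zero_curve(self):
        c = PeakCurve(t=np.arange(8.0), v=np.zeros(8), plane_index=0)
        assert vti(c) == 0.0

    @given(st.floats(0.1, 5.0))
    def test_linearity_in_velocity_scale(self, k):
        t = np.linspace(0.0, 800.0, 21)
        v = np.abs(np.sin(t / 100.0)) * 100.0
        c1 = PeakCurve(t=t, v=v, plane_index=0)
        ck = PeakCurve(t=t, v=k * v, plane_index=0)
        assert vti(ck) == pytest.approx(k * vti(c1), rel=1e-9)


class TestStrokeVolumeAndAVA:
    def test_uniform_flow_volume(self):
        plane = PlaneSpec(grid_nx=16, grid_ny=16, pixel_size=5.0, n_frames=8,
                          frame_dt=125.0)
        m = _synthetic_maps(plane, vz=10.0)
        roi = np.zeros((16, 16), bool)
        roi.flat[:40] = True  # 10 cm^2
        assert stroke_volume_pc(m, roi) == pytest.approx(100.0)

    def test_zero_flow(self, small_plane):
        m = _synthetic_maps(small_plane)
        assert stroke_volume_pc(m, np.ones((32, 32), bool)) == 0.0

    def test_empty_roi_rejected(self, small_plane):
        with pytest.raises(ValueError):
            stroke_volume_pc(_synthetic_maps(small_plane), np.zeros((32, 32), bool))

    def test_phantom_flux_matches_truth(self):
        plane = PlaneSpec()
        f = make_velocity_field(plane, [JetSpec(peak_speed=350.0)],
                                BaseFlow(peak_speed=60.0))
        truth = ground_truth_summary(f)
        m = _maps_from(f, venc=400.0)
        sv = stroke_volume_pc(m, f.lumen_mask)
        assert sv == pytest.approx(truth.true_sv, rel=0.02)

    @pytest.mark.parametrize("d, area", [(2.0, math.pi), (0.0, 0.0),
                                         (2.4, 1.44 * math.pi)])
    def test_lvot_area(self, d, area):
        assert lvot_area(d) == pytest.approx(area)

    def test_lvot_area_rejects_negative(self):
        with pytest.raises(ValueError):
            lvot_area(-1.0)

    def test_continuity_identities(self):
        assert ava_continuity(3.0, 20.0, 60.0) == pytest.approx(1.0)
        assert ava_continuity(2.7, 42.0, 42.0) == pytest.approx(2.7)
        assert ava_cine(60.0, 100.0) == pytest.approx(0.6)
        assert ava_flow(60.0, 100.0) == pytest.approx(0.6)
        for fn in (lambda: ava_continuity(3.0, 20.0, 0.0),
                   lambda: ava_cine(60.0, 0.0), lambda: ava_flow(60.0, -1.0)):
            with pytest.raises(ValueError):
                fn()


class TestQuantifySubject:
    def _pipeline(self, tilt=0.0, noise=0.0, peak=420.0, venc=500.0, seed=0,
                  base=60.0):
        plane = PlaneSpec()
        f = make_velocity_field(plane, [JetSpec(peak_speed=peak, tilt_polar=tilt)],
                                BaseFlow(peak_speed=base))
        m = _maps_from(f, venc=venc, noise=noise, seed=seed)
        return f, {0: m}, {0: f.lumen_mask}

    def test_aligned_severe_jet_recovered(self):
        f, maps, rois = self._pipeline()
        truth = ground_truth_summary(f)
        rep = quantify_subject(maps, rois, "3Dir", sv_cine=truth.true_sv)
        assert rep.vpeak == pytest.approx(truth.true_peak_speed / 100.0, rel=0.01)
        assert rep.pg == pytest.approx(4.0 * rep.vpeak**2, rel=1e-12)
        assert rep.vpeak >= rep.vmean
        assert rep.mg <= rep.pg

    def test_tilted_jet_1dir_underestimates_by_cosine(self):
        f, maps, rois = self._pipeline(tilt=25.0, base=0.0)
        truth = ground_truth_summary(f)
        rep = quantify_subject(maps, rois, "1Dir")
        expected = truth.true_peak_speed / 100.0 * math.cos(math.radians(25.0))
        assert rep.vpeak == pytest.approx(expected, rel=0.01)

    def test_modes_agree_for_aligned_jet(self):
        _, maps, rois = self._pipeline()
        r1 = quantify_subject(maps, rois, "1Dir")
        r3 = quantify_subject(maps, rois, "3Dir")
        assert r1.vpeak == pytest.approx(r3.vpeak, abs=1e-9)

    def test_aliased_plane_is_unwrapped_in_passing(self):
        f, maps, rois = self._pipeline(peak=280.0, venc=200.0, base=0.0)
        rep = quantify_subject(maps, rois, "3Dir")
        assert rep.vpeak == pytest.approx(2.8, rel=0.01)

    def test_unsalvageable_subject_raises(self):
        plane = PlaneSpec(grid_nx=48, grid_ny=48)
        f = make_velocity_field(plane, [JetSpec(peak_speed=300.0, sigma=5.0)])
        peak_frame = int(np.argmax(f.vz.reshape(f.vz.shape[0], -1).max(axis=1)))
        f.vz[:] = f.vz[peak_frame]  # wrapped in every frame, no anchor
        maps = {0: _maps_from(f, venc=200.0)}
        with pytest.raises(SalvageFailedError):
            quantify_subject(maps, {0: f.lumen_mask}, "3Dir")

    def test_invalid_mode_rejected(self):
        _, maps, rois = self._pipeline()
        with pytest.raises(ValueError, match="mode"):
            quantify_subject(maps, rois, "2Dir")
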