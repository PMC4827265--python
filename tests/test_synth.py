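"""Synthetic 4D generator: shapes, motion, banding, M-mode, Doppler."""

import numpy as np
import pytest

import oftflow as of
from oftflow.wallmotion import CLOSURE_GAP_THRESHOLD, mmode_fractions

from conftest import FAST_KW, fast_motion


class TestParams:
    def test_taper_invariant_enforced(self):
        with pytest.raises(ValueError):
            of.OftShapeParams(inlet_radius=100e-6, outlet_radius=120e-6)

    def test_cushion_amplitude_bounds(self):
        with pytest.raises(ValueError):
            of.OftShapeParams(cushion_amplitude=1.0)

    def test_band_validation(self):
        with pytest.raises(ValueError):
            of.BandParams(tightness=0.0)
        with pytest.raises(ValueError):
            of.BandParams(position=1.2)

    def test_frame_cadence_matches_acquisition(self):
        # heart rate 2.5 Hz, 56 frames: 7.14 ms spacing = 140 frames/s
        m = of.MotionParams()
        assert m.period_T == 0.4
        dt = m.period_T / m.n_frames
        assert dt == pytest.approx(1.0 / 140.0, rel=1e-3)


class TestGenerateMotion:
    def test_periodicity(self):
        times = np.array([0.0, 0.4])  # phase 0 and phase 1
        lumen, myo, _ = of.generate_motion(
            motion=fast_motion(), times=times, n_rings=12, n_theta=16
        )
        np.testing.assert_allclose(lumen[0].vertices, lumen[1].vertices, atol=1e-18)
        np.testing.assert_allclose(myo[0].vertices, myo[1].vertices, atol=1e-18)

    def test_connectivity_constant_across_frames(self, normal_sequence):
        lumen, myo, _ = normal_sequence
        shapes = {f.vertices.shape for f in lumen} | {f.vertices.shape for f in myo}
        assert len(shapes) == 1

    def test_no_motion_when_amplitude_zero(self):
        lumen, myo, _ = of.generate_motion(
            motion=fast_motion(expansion_amplitude=0.0), n_rings=10, n_theta=16
        )
        for f in lumen[1:]:
            np.testing.assert_array_equal(f.vertices, lumen[0].vertices)

    def test_ground_truth_recoverable_from_meshes(self, normal_sequence, normal_traces):
        _, _, gt = normal_sequence
        for i, tr in enumerate(normal_traces):
            a_rel = np.abs(tr.lumen_area - gt.lumen_area[i]) / gt.lumen_area[i].max()
            p_rel = (
                np.abs(tr.lumen_perimeter - gt.lumen_perimeter[i])
                / gt.lumen_perimeter[i].max()
            )
            m_rel = np.abs(tr.myocardium_area - gt.myo_area[i]) / gt.myo_area[i].max()
            assert a_rel.max() < 0.015
            assert p_rel.max() < 0.01
            assert m_rel.max() < 0.015

    def test_lumen_closes_and_reopens(self, normal_sequence):
        lumen, _, gt = normal_sequence
        mat = of.area_plot(lumen)
        ring_max = mat.max(axis=1)
        ring_min = mat.min(axis=1)
        # every ring closes to ~zero area and fully reopens (taper makes
        # distal ring maxima smaller than the global maximum)
        assert np.all(ring_min < 1e-3 * ring_max)
        assert np.all(ring_max > 0.3)

    def test_cushions_make_lumen_circular_then_elliptical_then_slit(self):
        lumen, _, _ = of.generate_motion(motion=fast_motion(), **FAST_KW)
        ring = lumen[0].n_rings // 2

        def anisotropy(j):
            v = lumen[j].vertices[ring]
            r = np.linalg.norm(v - v.mean(axis=0), axis=1)
            return r.max() / r.min()

        areas = np.array([f.ring_areas()[ring] for f in lumen])
        j_open = int(np.argmax(areas))
        partially = (areas > 0.15 * areas.max()) & (areas < 0.5 * areas.max())
        j_mid = int(np.flatnonzero(partially)[0])
        j_closed = int(np.argmin(areas))
        assert anisotropy(j_open) < 1.15  # near-circular when fully expanded
        assert anisotropy(j_mid) > 1.5  # elliptical while contracting
        assert areas[j_closed] < 1e-3 * areas.max()  # slit: area collapses

    def test_seeded_jitter_is_deterministic_and_varies(self):
        kw = dict(motion=fast_motion(n_frames=8), n_rings=8, n_theta=12, jitter=0.05)
        a1, _, _ = of.generate_motion(seed=3, **kw)
        a2, _, _ = of.generate_motion(seed=3, **kw)
        b, _, _ = of.generate_motion(seed=4, **kw)
        np.testing.assert_array_equal(a1[0].vertices, a2[0].vertices)
        assert not np.allclose(a1[0].vertices, b[0].vertices)


class TestBanding:
    def test_band_halves_max_radius_with_full_suppression(self):
        # ring 4 of 21 sits exactly at the band station (0.2)
        kw = dict(motion=fast_motion(), n_rings=21, n_theta=24)
        band = of.BandParams(position=0.2, tightness=0.5, motion_suppression=1.0)
        lum_n, _, _ = of.generate_motion(**kw)
        lum_b, _, _ = of.generate_motion(band=band, **kw)
        ring = 4

        def max_radius(frames):
            return max(
                np.linalg.norm(
                    f.vertices[ring] - f.vertices[ring].mean(axis=0), axis=1
                ).max()
                for f in frames
            )

        ratio = max_radius(lum_b) / max_radius(lum_n)
        assert ratio == pytest.approx(0.5, rel=0.01)

    def test_band_monotone_in_tightness(self):
        kw = dict(motion=fast_motion(n_frames=16), n_rings=21, n_theta=16)
        areas = []
        for tight in (0.9, 0.7, 0.5, 0.3):
            band = of.BandParams(position=0.2, tightness=tight, motion_suppression=1.0)
            lum, _, _ = of.generate_motion(band=band, **kw)
            areas.append(max(f.ring_areas()[4] for f in lum))
        assert np.all(np.diff(areas) < 0)

    def test_neutral_band_is_bit_identical_to_no_band(self):
        kw = dict(motion=fast_motion(n_frames=8), n_rings=10, n_theta=12)
        lum_n, myo_n, _ = of.generate_motion(**kw)
        neutral = of.BandParams(tightness=1.0, motion_suppression=0.0)
        lum_b, myo_b, _ = of.generate_motion(band=neutral, **kw)
        for a, b in zip(lum_n + myo_n, lum_b + myo_b):
            np.testing.assert_array_equal(a.vertices, b.vertices)

    def test_banded_area_reduced_only_near_band(self, normal_sequence, banded_sequence):
        lum_n = normal_sequence[0]
        lum_b = banded_sequence[0]
        max_n = of.area_plot(lum_n, normalization_area=1.0).max(axis=1)
        max_b = of.area_plot(lum_b, normalization_area=1.0).max(axis=1)
        nr = len(max_n)
        band_ring = int(round(0.2 * (nr - 1)))
        assert max_b[band_ring] < 0.75 * max_n[band_ring]
        distal = slice(int(0.6 * nr), nr)
        np.testing.assert_allclose(max_b[distal], max_n[distal], rtol=1e-9)


class TestMMode:
    def test_constant_gap_for_motionless_tube(self):
        lumen, _, _ = of.generate_motion(
            motion=fast_motion(expansion_amplitude=0.0), n_rings=12, n_theta=16
        )
        mm = of.generate_mmode(lumen, station=0.5)
        assert np.ptp(mm.gap) < 1e-9
        assert mm.gap[0] > 0

    def test_closed_fraction_recovers_thresholded_ground_truth(self, normal_sequence):
        lumen, _, gt = normal_sequence
        mm = of.generate_mmode(lumen, station=0.5, times=gt.times, period=gt.period)
        _, _, closed = mmode_fractions(mm)
        expected = gt.closed_fraction_at_threshold(2, CLOSURE_GAP_THRESHOLD)
        one_frame = 1.0 / len(gt.times)
        assert closed == pytest.approx(expected, abs=one_frame)
        # and the thresholded observable sits within ~1.5 frames of the
        # prescribed geometric closure fraction
        assert expected == pytest.approx(gt.motion.closure_fraction, abs=1.5 * one_frame)

    def test_gap_zero_during_prescribed_closure(self, normal_sequence):
        lumen, _, gt = normal_sequence
        mm = of.generate_mmode(lumen, station=0.5, times=gt.times, period=gt.period)
        closed_frames = gt.closed[2]
        assert np.all(mm.gap[closed_frames] <= CLOSURE_GAP_THRESHOLD)
        assert np.all(mm.gap >= 0)

    def test_banded_gap_reduced_at_band_station(self, normal_sequence, banded_sequence):
        lum_n, _, gt_n = normal_sequence
        lum_b, _, _ = banded_sequence
        mm_n = of.generate_mmode(lum_n, station=0.2, times=gt_n.times)
        mm_b = of.generate_mmode(lum_b, station=0.2, times=gt_n.times)
        assert mm_b.gap.max() < mm_n.gap.max()

    def test_line_missing_tube_raises(self, normal_sequence):
        lumen, _, _ = normal_sequence
        with pytest.raises(ValueError):
            of.generate_mmode(
                lumen, line=(np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0, 0.0]))
            )


class TestDoppler:
    @pytest.fixture(scope="class")
    def small_cfd(self):
        lumen, _, gt = of.generate_motion(
            motion=fast_motion(n_frames=12), n_rings=12, n_theta=16
        )
        return lumen, gt

    def test_zero_dp_gives_zero_vz(self, small_cfd):
        lumen, gt = small_cfd
        trace = of.synthesize_doppler(
            lumen, np.zeros_like(gt.dp), gt.probe_point, gt.times, n_radial=3
        )
        assert np.all(trace.vz == 0.0)
        assert np.array_equal(trace.no_flow, gt.no_flow)

    def test_stokes_linearity_in_dp(self, small_cfd):
        # sub-aliasing amplitudes so the pre-wrap velocities are compared
        lumen, gt = small_cfd
        t1 = of.synthesize_doppler(
            lumen, 0.2 * gt.dp, gt.probe_point, gt.times, n_radial=3
        )
        t2 = of.synthesize_doppler(
            lumen, 0.4 * gt.dp, gt.probe_point, gt.times, n_radial=3
        )
        assert not t1.wrapped.any() and not t2.wrapped.any()
        np.testing.assert_allclose(t2.vz, 2.0 * t1.vz, rtol=1e-9, atol=1e-15)

    def test_fast_flow_emerges_wrapped(self, small_cfd):
        lumen, gt = small_cfd
        trace = of.synthesize_doppler(
            lumen, 3.0 * gt.dp, gt.probe_point, gt.times, n_radial=3
        )
        alias = trace.acquisition.aliasing_velocity
        assert trace.wrapped.any()
        assert np.abs(trace.vz).max() <= alias + 1e-15

    def test_probe_outside_lumen_raises(self, small_cfd):
        lumen, gt = small_cfd
        far = gt.probe_point + np.array([0.0, 5e-3, 0.0])
        with pytest.raises(ValueError):
            of.synthesize_doppler(lumen, gt.dp, far, gt.times, n_radial=3)
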