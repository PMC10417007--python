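"""Unit and property tests for the vessel tortuosity index."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from octavti.tortuosity import (
    arc_chord,
    chord_frame,
    compute_vti,
    critical_points,
    image_mean_vti,
    inter_inflection_ratio,
    resample_polyline,
    smooth_polyline,
    tangent_angle_sd,
)
from oracles import brute_force_vti


def sine_points(amplitude, period, n_periods, n=4000):
    x = np.linspace(0.0, n_periods * period, n)
    return np.column_stack([x, amplitude * np.sin(2 * np.pi * x / period)])


def semicircle_points(radius, n=1000):
    t = np.linspace(0.0, np.pi, n)
    return np.column_stack([radius * np.cos(t), radius * np.sin(t)])


class TestArcChord:
    def test_collinear_points(self):
        pts = np.column_stack([np.linspace(0, 100, 101), np.zeros(101)])
        la, lc = arc_chord(pts)
        assert la == pytest.approx(100.0)
        assert lc == pytest.approx(100.0)

    def test_semicircle_ratio_is_half_pi(self):
        la, lc = arc_chord(semicircle_points(50.0))
        assert la / lc == pytest.approx(np.pi / 2, abs=1e-3)

    def test_sine_ratio_matches_quadrature(self):
        # one period of y = sin x: arc length by quadrature over chord 2*pi
        expected, _ = integrate.quad(lambda x: np.hypot(1, np.cos(x)), 0, 2 * np.pi)
        pts = sine_points(1.0, 2 * np.pi, 1, n=2000)
        la, lc = arc_chord(pts)
        assert la / lc == pytest.approx(expected / (2 * np.pi), abs=1e-3)
        assert la / lc == pytest.approx(1.2160, abs=1e-3)

    def test_closed_loop_rejected(self):
        t = np.linspace(0, 2 * np.pi, 100)
        circle = np.column_stack([np.cos(t), np.sin(t)])
        with pytest.raises(ValueError, match="loop"):
            arc_chord(circle)


class TestChordFrame:
    def test_last_point_lands_on_x_axis(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(40, 2)).cumsum(axis=0)
        out = chord_frame(pts)
        _, lc = arc_chord(pts)
        assert out[0] == pytest.approx([0.0, 0.0], abs=1e-12)
        assert out[-1] == pytest.approx([lc, 0.0], abs=1e-9)

    def test_already_aligned_is_identity(self):
        pts = np.column_stack([np.linspace(0, 10, 20), np.sin(np.linspace(0, 3, 20)) * 0.0])
        assert np.allclose(chord_frame(pts), pts, atol=1e-12)

    def test_isometry(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(30, 2)).cumsum(axis=0)
        out = chord_frame(pts)
        d_in = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d_out = np.linalg.norm(out[:, None] - out[None, :], axis=-1)
        assert np.allclose(d_in, d_out, rtol=1e-9, atol=1e-9)


class TestCriticalPoints:
    def test_straight_line_has_none(self):
        pts = np.column_stack([np.linspace(0, 50, 60), np.zeros(60)])
        _, n = critical_points(pts)
        assert n == 0

    @pytest.mark.parametrize("n_periods, expected", [(1, 2), (2, 4), (3, 6)])
    def test_sine_extrema_count(self, n_periods, expected):
        pts = resample_polyline(sine_points(20.0, 200.0, n_periods), 1.0)
        _, n = critical_points(pts)
        assert n == expected

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            critical_points(np.zeros((4, 2)))


class TestTangentAngleSD:
    def test_straight_line_zero(self):
        pts = np.column_stack([np.linspace(0, 50, 60), np.linspace(0, 20, 60)])
        assert tangent_angle_sd(pts) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_arc_constant_turning(self):
        # equal angular steps -> constant angle difference -> SD 0
        assert tangent_angle_sd(semicircle_points(50.0, n=500)) == pytest.approx(0.0, abs=1e-9)

    def test_zigzag_matches_enumeration(self):
        # alternating turns +10, -10 deg at every second sample: the
        # difference sequence alternates 0, +10, 0, -10, ... whose
        # population SD is enumerable by hand
        turns = np.deg2rad(np.array([0, 10, 0, -10] * 10, dtype=float))
        headings = np.concatenate([[0.0], np.cumsum(turns)])
        steps = np.column_stack([np.cos(headings), np.sin(headings)])
        pts = np.concatenate([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
        expected = float(np.std(np.degrees(turns)))
        assert tangent_angle_sd(pts) == pytest.approx(expected, rel=1e-9)

    def test_radian_output_scales(self):
        pts = sine_points(10.0, 100.0, 2, n=500)
        assert tangent_angle_sd(pts, "deg") == pytest.approx(
            np.degrees(tangent_angle_sd(pts, "rad")), rel=1e-12
        )


class TestInterInflectionRatio:
    def test_straight_line_fallback(self):
        pts = np.column_stack([np.linspace(0, 50, 60), np.zeros(60)])
        assert inter_inflection_ratio(pts, []) == pytest.approx(1.0, abs=1e-12)

    def test_semicircle_quarter_pieces(self):
        # chord-framed semicircle splits at the apex into two quarter arcs;
        # quarter arc/chord ratio = (pi*r/2) / (r*sqrt(2))
        framed = resample_polyline(chord_frame(semicircle_points(50.0, 4000)), 0.25)
        idx, n = critical_points(framed)
        assert n == 1
        expected = (np.pi / 2) / np.sqrt(2.0)
        assert inter_inflection_ratio(framed, idx) == pytest.approx(expected, rel=1e-3)

    def test_sine_pieces_match_quadrature(self):
        period = 200.0
        amp = 20.0
        pts = resample_polyline(sine_points(amp, period, 1, n=8000), 0.5)
        idx, n = critical_points(pts)
        assert n == 2
        w = 2 * np.pi / period

        def piece_ratio(x0, x1):
            arc, _ = integrate.quad(lambda x: np.hypot(1, amp * w * np.cos(w * x)), x0, x1)
            chord = np.hypot(x1 - x0, amp * (np.sin(w * x1) - np.sin(w * x0)))
            return arc / chord

        expected = np.mean(
            [piece_ratio(0, period / 4), piece_ratio(period / 4, 3 * period / 4),
             piece_ratio(3 * period / 4, period)]
        )
        assert inter_inflection_ratio(pts, idx) == pytest.approx(expected, rel=5e-3)


class TestComputeVti:
    def test_straight_segment_is_exactly_zero(self):
        pts = np.column_stack([np.linspace(0, 300, 400), np.zeros(400)])
        assert compute_vti(pts).vti == 0.0

    def test_uniform_arc_near_zero(self):
        # constant curvature: angle differences constant, SD ~ 0
        m = compute_vti(semicircle_points(50.0, 2000))
        assert m.n_critical == 1
        assert m.vti == pytest.approx(0.0, abs=1e-3)

    @pytest.mark.parametrize(
        "amplitude, period, n_periods",
        [(30.0, 300.0, 2), (15.0, 200.0, 3), (40.0, 350.0, 2)],
    )
    def test_sine_agrees_with_brute_force_oracle(self, amplitude, period, n_periods):
        w = 2 * np.pi / period
        oracle = brute_force_vti(
            lambda t: t, lambda t: amplitude * np.sin(w * t), 0.0, n_periods * period
        )
        m = compute_vti(sine_points(amplitude, period, n_periods))
        assert m.n_critical == oracle["N"]
        assert m.vti == pytest.approx(oracle["VTI"], rel=0.02)

    def test_monotone_in_number_of_periods(self):
        # more angles along a fixed chord -> strictly larger index
        values = [
            compute_vti(sine_points(20.0, 800.0 / k, k, n=6000)).vti for k in range(1, 9)
        ]
        assert all(b > a for a, b in zip(values, values[1:]))

    @settings(max_examples=20, deadline=None)
    @given(
        angle=st.floats(-np.pi, np.pi),
        tx=st.floats(-200, 200),
        ty=st.floats(-200, 200),
    )
    def test_rigid_motion_invariance(self, angle, tx, ty):
        pts = sine_points(25.0, 250.0, 2, n=1500)
        rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        moved = pts @ rot.T + np.array([tx, ty])
        m0 = compute_vti(pts)
        m1 = compute_vti(moved)
        assert m1.vti == pytest.approx(m0.vti, abs=1e-6, rel=1e-6)

    def test_scale_invariance_with_scaled_spacing(self):
        # the index is dimensionless once the angle-sampling interval is
        # expressed in units of the curve scale
        pts = sine_points(25.0, 250.0, 2, n=3000)
        m0 = compute_vti(pts, spacing=1.0)
        m2 = compute_vti(pts * 2.0, spacing=2.0)
        assert m2.vti == pytest.approx(m0.vti, rel=0.02)

    def test_zero_law(self):
        # VTI = 0 iff N = 0 or SD_theta = 0
        straight = compute_vti(np.column_stack([np.linspace(0, 100, 200), np.zeros(200)]))
        assert straight.n_critical == 0 and straight.vti == 0.0
        wavy = compute_vti(sine_points(20.0, 200.0, 2))
        assert wavy.n_critical > 0 and wavy.sd_theta > 0 and wavy.vti > 0


class TestImageMeanVti:
    def test_mean_of_values(self):
        a = compute_vti(sine_points(20.0, 200.0, 2))
        b = compute_vti(np.column_stack([np.linspace(0, 100, 200), np.zeros(200)]))
        assert image_mean_vti([a, b]) == pytest.approx((a.vti + b.vti) / 2, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no measurable segments"):
            image_mean_vti([])


class TestHelpers:
    def test_resample_uniform_spacing(self):
        pts = sine_points(20.0, 200.0, 2)
        out = resample_polyline(pts, 1.0)
        steps = np.linalg.norm(np.diff(out, axis=0), axis=1)
        assert steps.std() / steps.mean() < 0.01

    def test_smooth_identity_window_one(self):
        pts = sine_points(5.0, 50.0, 1, n=100)
        assert np.array_equal(smooth_polyline(pts, 1), pts)

    def test_smooth_keeps_endpoints(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(50, 2)).cumsum(axis=0)
        sm = smooth_polyline(pts, 7)
        assert np.allclose(sm[[0, -1]], pts[[0, -1]])
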