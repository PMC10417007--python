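"""Tests for the synthetic vessel/cohort generator."""

import numpy as np
import pytest
from scipy import integrate

from octavti.synthetic import (
    CohortConfig,
    GroupSpec,
    RenderConfig,
    TABLE1_GROUPS,
    make_curve,
    render_image,
    simulate_cohort,
    truncated_normal_moments,
)
from conftest import render_single_sine


class TestMakeCurve:
    def test_line_identity(self):
        c = make_curve("line", {"x0": 0, "y0": 0, "x1": 100, "y1": 0}, 101)
        assert c.truth.arc_length == pytest.approx(100.0)
        assert c.truth.chord_length == pytest.approx(100.0)
        assert c.truth.inflection_count == 0

    def test_semicircle_geometry(self):
        c = make_curve("circular_arc", {"radius": 50, "angle": np.pi}, 1000)
        assert c.truth.arc_length / c.truth.chord_length == pytest.approx(np.pi / 2, rel=1e-9)

    def test_sine_arc_chord_ratio_from_quadrature(self):
        expected, _ = integrate.quad(lambda x: np.hypot(1, np.cos(x)), 0, 2 * np.pi)
        c = make_curve("sine", {"amplitude": 1, "period": 2 * np.pi, "n_periods": 1}, 2000)
        assert c.truth.arc_length / c.truth.chord_length == pytest.approx(
            expected / (2 * np.pi), rel=1e-6
        )
        assert c.truth.inflection_count == 2

    def test_zigzag_exact_lengths(self):
        c = make_curve("zigzag", {"amplitude": 10, "period": 40, "n_periods": 3}, 2000)
        per_quarter = np.hypot(10.0, 10.0)
        assert c.truth.arc_length == pytest.approx(12 * per_quarter, rel=1e-9)
        assert c.truth.chord_length == pytest.approx(120.0)
        assert c.truth.inflection_count == 6

    @pytest.mark.parametrize(
        "kind",
        ["line", "circular_arc", "sine", "zigzag", "random_spline"],
    )
    def test_polyline_length_tracks_analytic(self, kind):
        params = {
            "line": {"x0": 0, "y0": 0, "x1": 150, "y1": 70},
            "circular_arc": {"radius": 80, "angle": 2.0},
            "sine": {"amplitude": 25, "period": 240, "n_periods": 2},
            "zigzag": {"amplitude": 15, "period": 60, "n_periods": 4},
            "random_spline": {"length": 400, "amplitude": 30, "n_control": 8, "seed": 5},
        }[kind]
        c = make_curve(kind, params)
        steps = np.linalg.norm(np.diff(c.points, axis=0), axis=1)
        assert steps.sum() == pytest.approx(c.truth.arc_length, rel=1e-3)
        assert c.truth.arc_length >= c.truth.chord_length - 1e-9
        assert np.all(steps > 0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown curve kind"):
            make_curve("helix", {}, 100)

    @pytest.mark.parametrize(
        "kind, params",
        [
            ("circular_arc", {"radius": 0, "angle": 1.0}),
            ("sine", {"amplitude": 1, "period": 0, "n_periods": 1}),
            ("line", {"x0": 5, "y0": 5, "x1": 5, "y1": 5}),
        ],
    )
    def test_degenerate_params_rejected(self, kind, params):
        with pytest.raises(ValueError):
            make_curve(kind, params)


class TestRenderImage:
    def test_zero_curves_uniform_background(self):
        cfg = RenderConfig(image_size=64, background_level=0.07)
        img, gt = render_image([], cfg)
        assert img.shape == (64, 64)
        assert np.all(img == pytest.approx(0.07))
        assert gt["curves"] == []

    def test_noise_free_straight_vessel_peak_on_centerline(self):
        row = 40.0
        c = make_curve("line", {"x0": 10, "y0": row, "x1": 110, "y1": row}, 300)
        cfg = RenderConfig(image_size=128, vessel_profile_sigma=2.0, noise_sigma=0.0)
        img, _ = render_image([c], cfg)
        for col in range(20, 100):
            assert abs(int(np.argmax(img[:, col])) - row) <= 0.5

    def test_seeded_noise_is_deterministic(self):
        curves = [
            make_curve("sine", {"amplitude": 10, "period": 80, "n_periods": 2}, 800).translated(
                30, 60 + 40 * i
            )
            for i in range(3)
        ]
        cfg = RenderConfig(image_size=256, noise_sigma=0.02, seed=11)
        img1, _ = render_image(curves, cfg)
        img2, _ = render_image(curves, cfg)
        assert img1.tobytes() == img2.tobytes()
        img3, _ = render_image(curves, RenderConfig(image_size=256, noise_sigma=0.02, seed=12))
        assert img1.tobytes() != img3.tobytes()

    def test_noise_free_renders_identical_across_seeds(self):
        c = make_curve("line", {"x0": 10, "y0": 30, "x1": 100, "y1": 30}, 200)
        a, _ = render_image([c], RenderConfig(image_size=128, seed=1))
        b, _ = render_image([c], RenderConfig(image_size=128, seed=2))
        assert np.array_equal(a, b)

    def test_out_of_canvas_curve_rejected(self):
        c = make_curve("line", {"x0": -5, "y0": 10, "x1": 50, "y1": 10}, 100)
        with pytest.raises(ValueError, match="indices \\[0\\]"):
            render_image([c], RenderConfig(image_size=64))

    def test_ground_truth_contains_vti(self):
        _, gt = render_single_sine(20.0, 250.0, 2, size=1024)
        rec = gt["curves"][0]
        assert rec["vti"] > 0
        assert rec["metrics"]["N"] == 4


class TestSimulateCohort:
    def test_study_sized_cohort_has_56_rows(self):
        table = simulate_cohort(CohortConfig(seed=3))
        assert len(table) == 56
        assert list(table.columns) == ["subject_id", "group", "onset", "sex", "age", "mean_vti"]
        counts = table["group"].value_counts()
        assert counts["classic_male"] == 5 and counts["late_female"] == 7

    def test_zero_variance_group_is_constant(self):
        grp = GroupSpec("g", "healthy", "male", 10, 0.25, 0.0, 40.0, 0.0)
        table = simulate_cohort(CohortConfig(groups=(grp,), seed=0))
        assert np.all(table["mean_vti"] == 0.25)
        assert np.all(table["age"] == 40.0)

    def test_grand_mean_matches_weighted_group_means(self):
        # closed-form expectation: weighted average of (truncated) means
        weights = np.array([g.n for g in TABLE1_GROUPS], dtype=float)
        means = np.array(
            [truncated_normal_moments(g.vti_mean, g.vti_sd, 0.0)[0] for g in TABLE1_GROUPS]
        )
        expected = float((weights * means).sum() / weights.sum())
        sims = [
            simulate_cohort(CohortConfig(seed=s))["mean_vti"].mean() for s in range(0, 25000, 100)
        ]
        grand = float(np.mean(sims))
        mc_se = float(np.std(sims) / np.sqrt(len(sims)))
        assert abs(grand - expected) < 4 * mc_se + 1e-4

    def test_large_sample_converges_to_truncated_moments(self):
        grp = GroupSpec("g", "late", "female", 10_000, 0.19, 0.03, 38.1, 21.8)
        table = simulate_cohort(CohortConfig(groups=(grp,), seed=9))
        vm, vs = truncated_normal_moments(0.19, 0.03, 0.0)
        am, asd = truncated_normal_moments(38.1, 21.8, 16.0)
        assert table["mean_vti"].mean() == pytest.approx(vm, rel=0.02)
        assert table["mean_vti"].std() == pytest.approx(vs, rel=0.02)
        assert table["age"].mean() == pytest.approx(am, rel=0.02)
        assert table["age"].std() == pytest.approx(asd, rel=0.02)
        assert table["age"].min() >= 16.0
        assert table["mean_vti"].min() >= 0.0

    def test_reproducible_under_seed(self):
        a = simulate_cohort(CohortConfig(seed=21))
        b = simulate_cohort(CohortConfig(seed=21))
        assert a.equals(b)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(groups=())
        with pytest.raises(ValueError):
            GroupSpec("g", "healthy", "male", 0, 0.2, 0.1, 40, 10)
        with pytest.raises(ValueError):
            GroupSpec("g", "healthy", "male", 5, 0.2, -0.1, 40, 10)

    def test_full_images_mode_tunes_vessels_to_target(self):
        grp = GroupSpec("g", "healthy", "male", 1, 0.25, 0.0, 40.0, 0.0)
        table, images = simulate_cohort(
            CohortConfig(groups=(grp,), seed=4, mode="full_images"),
            render_config=RenderConfig(image_size=1024),
        )
        assert len(images) == 1
        img, gt = images[table["subject_id"].iloc[0]]
        assert img.shape == (1024, 1024)
        true_mean = float(np.mean([c["vti"] for c in gt["curves"]]))
        assert true_mean == pytest.approx(0.25, rel=0.05)
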