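import numpy as np
import pytest

from trichocount import (
    ContourConfig,
    CountResult,
    CurveProfile,
    SceneSpec,
    count_annotated_contour,
    count_annotated_intersection,
    count_auto_contour,
    count_curve_intersections,
    count_endpoints,
    compute_offset,
    detect_base_curve,
    generate_scene,
    preprocess_pipeline,
    to_profile,
    translate_curve,
)
from trichocount.errors import EmptyMaskError, TrichocountError

from oracles import count_crossings_bruteforce


def vertical_lines(cols, top, base_row, shape=(120, 100)):
    """Skeleton of disjoint 1-px vertical lines plus a base line."""
    skel = np.zeros(shape, bool)
    skel[base_row, :] = True
    for c in cols:
        skel[top:base_row, c] = True
    return skel


class TestCountEndpoints:
    def test_single_line_counts_one(self):
        skel = np.zeros((100, 60), bool)
        skel[90, :] = True
        skel[60:91, 30] = True
        base = CurveProfile.constant(90, 60)
        assert count_endpoints(skel, base).count == 1.0

    def test_empty_skeleton_is_zero_with_warning(self):
        with pytest.warns(UserWarning):
            result = count_endpoints(np.zeros((50, 50), bool), CurveProfile.constant(40, 50))
        assert result.count == 0.0

    def test_border_endpoints_excluded(self):
        skel = vertical_lines([2, 30, 97], top=40, base_row=90)
        base = CurveProfile.constant(90, 100)
        assert count_endpoints(skel, base, ContourConfig(border_margin=5)).count == 1.0

    def test_simulator_scene_matches_truth(self):
        spec = SceneSpec.noiseless(12, seed=11)
        img, truth = generate_scene(spec)
        skel = preprocess_pipeline(img)
        result = count_endpoints(skel, detect_base_curve(skel))
        assert result.count == 12.0


class TestDetectBaseCurve:
    def test_horizontal_line_constant_profile(self):
        skel = np.zeros((100, 40), bool)
        skel[90, :] = True
        profile = detect_base_curve(skel)
        assert (profile.rows == 90).all()

    def test_gap_interpolated_linearly(self):
        skel = np.zeros((120, 100), bool)
        skel[90, 0:20] = True
        skel[95, 70:100] = True
        rows = detect_base_curve(skel).interpolated()
        # gap spans columns 19..70 with rows 90 -> 95
        expected = 90 + (95 - 90) * (np.arange(20, 70) - 19) / (70 - 19)
        np.testing.assert_allclose(rows[20:70], expected)

    def test_simulator_base_within_2px(self, clean_scene):
        _, img, truth = clean_scene
        skel = preprocess_pipeline(img)
        detected = detect_base_curve(skel).interpolated()
        np.testing.assert_allclose(detected, truth.base_profile.rows, atol=2.0)

    def test_empty_errors(self):
        with pytest.raises(EmptyMaskError):
            detect_base_curve(np.zeros((10, 10), bool))


class TestComputeOffset:
    def test_interior_and_inclusive(self):
        skel = np.zeros((150, 30), bool)
        skel[20, 5] = skel[120, 5] = True
        assert compute_offset(skel, ContourConfig(offset_mode="interior")) == 20.0
        assert compute_offset(skel, ContourConfig(offset_mode="inclusive")) == 25.0

    def test_flat_scene_offset_near_length_over_five(self):
        spec = SceneSpec.noiseless(10, seed=5, filament_length_mean=60.0)
        img, _ = generate_scene(spec)
        skel = preprocess_pipeline(img)
        offset = compute_offset(skel, ContourConfig(n_curves=4))
        assert offset == pytest.approx(60.0 / 5, rel=0.10)

    def test_single_row_errors(self):
        skel = np.zeros((20, 20), bool)
        skel[10, :] = True
        with pytest.raises(TrichocountError):
            compute_offset(skel)


class TestTranslateCurve:
    def test_constant_shift(self):
        profile = CurveProfile.constant(90, 50)
        assert (translate_curve(profile, 20).rows == 70).all()

    def test_clipped_at_zero(self):
        profile = CurveProfile.constant(10, 50)
        assert (translate_curve(profile, 25).rows == 0).all()

    def test_slope_preserved(self):
        rows = np.linspace(40, 90, 60)
        shifted = translate_curve(CurveProfile(rows), 15).rows
        np.testing.assert_allclose(np.diff(shifted), np.diff(rows))


class TestCurveIntersections:
    def test_disjoint_lines_counted_separately(self):
        skel = vertical_lines([10, 20, 35, 50, 65, 80, 92], top=30, base_row=110)
        curve = CurveProfile.constant(70, 100)
        assert count_curve_intersections(skel, curve) == 7

    def test_tangent_run_counts_once(self):
        skel = np.zeros((60, 80), bool)
        skel[30, 40:45] = True  # tangent along the curve for 5 columns
        curve = CurveProfile.constant(30, 80)
        assert count_curve_intersections(skel, curve) == 1

    def test_gap_tolerance_merges_nearby_runs(self):
        skel = np.zeros((60, 80), bool)
        skel[20:41, 40] = True
        skel[20:41, 45] = True  # touch runs 39-41 and 44-46: 2-column gap
        curve = CurveProfile.constant(30, 80)
        assert count_curve_intersections(skel, curve, ContourConfig(gap_tolerance=2)) == 1
        assert count_curve_intersections(skel, curve, ContourConfig(gap_tolerance=1)) == 2

    def test_matches_component_label_oracle(self, rng):
        cfg = ContourConfig(gap_tolerance=2, border_margin=5)
        for _ in range(30):
            skel = rng.random((40, 60)) < 0.05
            steps = rng.integers(-1, 2, size=60)
            rows = np.clip(20 + np.cumsum(steps), 2, 37).astype(float)
            curve = CurveProfile(rows)
            expected = count_crossings_bruteforce(skel, rows, 2, 5)
            assert count_curve_intersections(skel, curve, cfg) == expected


class TestContourMethods:
    def test_equal_filaments_count_exact(self):
        spec = SceneSpec.noiseless(10, seed=21)
        img, _ = generate_scene(spec)
        skel = preprocess_pipeline(img)
        result = count_auto_contour(skel)
        assert result.count == 10.0
        assert result.per_curve_counts == [10, 10, 10, 10]

    def test_empty_skeleton_errors(self):
        with pytest.raises(EmptyMaskError):
            count_auto_contour(np.zeros((40, 40), bool))

    def test_mean_consistency(self, clean_scene):
        _, img, _ = clean_scene
        skel = preprocess_pipeline(img)
        result = count_auto_contour(skel)
        assert result.count == pytest.approx(np.mean(result.per_curve_counts), abs=1e-12)

    def test_low_occlusion_density_sweep_within_15pct(self):
        """Auto contouring tracks truth within 15% on low-occlusion scenes
        of near-uniform trichome length (the regime where every contour
        curve can reach every trichome)."""
        for n, seed in [(10, 31), (25, 32), (40, 33)]:
            spec = SceneSpec.noiseless(n, seed=seed, occlusion_bias=0.05)
            img, truth = generate_scene(spec)
            skel = preprocess_pipeline(img)
            count = count_auto_contour(skel).count
            assert count == pytest.approx(truth.count, rel=0.15)

    def test_undercounts_under_length_heterogeneity(self):
        """With realistic length variation the upper contour curves pass
        above the shorter trichomes, so the method undercounts."""
        counts, truths = [], []
        for n, seed in [(20, 61), (40, 62)]:
            img, truth = generate_scene(SceneSpec(n_trichomes=n, seed=seed))
            counts.append(count_auto_contour(preprocess_pipeline(img)).count)
            truths.append(truth.count)
        assert all(c <= t for c, t in zip(counts, truths))
        assert sum(counts) < sum(truths)

    def test_annotated_equals_auto_when_base_identical(self, clean_scene):
        _, img, _ = clean_scene
        skel = preprocess_pipeline(img)
        base = detect_base_curve(skel)
        auto = count_auto_contour(skel)
        annotated = count_annotated_contour(skel, base)
        assert annotated.count == auto.count
        assert annotated.per_curve_counts == auto.per_curve_counts

    def test_true_base_beats_corrupted_base_on_wavy_scene(self):
        """Emulates failed base detection on an uneven leaf surface: a base
        curve that is wrong over a block of columns drags every translated
        curve to the wrong height there."""
        spec = SceneSpec.noiseless(20, seed=41, base_amplitude=10.0)
        img, truth = generate_scene(spec)
        skel = preprocess_pipeline(img)
        good = count_annotated_contour(skel, truth.base_profile).count
        corrupted_rows = truth.base_profile.rows.copy()
        W = corrupted_rows.size
        corrupted_rows[W // 3 : 2 * W // 3] -= 40.0
        bad = count_annotated_contour(skel, CurveProfile(corrupted_rows)).count
        assert abs(good - truth.count) < abs(bad - truth.count)


class TestAnnotatedIntersection:
    def test_oracle_curve_recovers_truth(self, clean_scene):
        _, img, truth = clean_scene
        skel = preprocess_pipeline(img)
        curve = to_profile(truth.oracle_curve, skel.shape[1], skel.shape[0])
        assert count_annotated_intersection(skel, curve).count == truth.count

    def test_curve_above_tips_counts_zero(self, clean_scene):
        _, img, _ = clean_scene
        skel = preprocess_pipeline(img)
        curve = CurveProfile.constant(5, skel.shape[1])
        assert count_annotated_intersection(skel, curve).count == 0.0

    def test_occlusion_hides_endpoints_but_not_intersections(self):
        spec = SceneSpec(n_trichomes=4, occlusion_bias=0.67, min_root_spacing=40.0,
                         angle_sd=2.0, base_amplitude=0.0, filament_length_sd=0.0,
                         seed=51)
        img, truth = generate_scene(spec)
        skel = preprocess_pipeline(img)
        curve = to_profile(truth.oracle_curve, skel.shape[1], skel.shape[0])
        exact = count_annotated_intersection(skel, curve).count
        endpoints = count_endpoints(skel, detect_base_curve(skel)).count
        assert exact == truth.count
        assert endpoints < truth.count


class TestCountResult:
    def test_mean_mismatch_rejected(self):
        with pytest.raises(TrichocountError):
            CountResult(method="auto_contour", count=3.0, per_curve_counts=[1, 2], n_curves=2)

    def test_negative_count_rejected(self):
        with pytest.raises(TrichocountError):
            CountResult(method="endpoints", count=-1.0)
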