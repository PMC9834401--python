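"""Cortical-intensity profiling: ellipse fit, radial scan, averaging,
background correction and localisation classification."""

import numpy as np
import pytest

from mitoquant import cortex_profile, synthgen
from mitoquant.cortex_profile import (
    CorticalProfile,
    FittedEllipse,
    average_profiles,
    classify_localisation,
    fit_ellipse,
    scan_cortex,
    subtract_background,
    tabulate_categories,
)
from mitoquant.errors import DegenerateGeometryError, OutOfBoundsError

from conftest import classify_scene


def ellipse_points(center, a, b, theta_deg, n=100):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    c, s = np.cos(np.radians(theta_deg)), np.sin(np.radians(theta_deg))
    x = a * np.cos(t)
    y = b * np.sin(t)
    return np.column_stack([center[0] + c * x - s * y, center[1] + s * x + c * y])


class TestFitEllipse:
    def test_circle_recovered_exactly(self):
        pts = ellipse_points((50, 50), 10, 10, 0)
        e = fit_ellipse(pts)
        assert e.center == pytest.approx((50, 50), abs=1e-6)
        assert e.semi_major == pytest.approx(10, abs=1e-6)
        assert e.semi_minor == pytest.approx(10, abs=1e-6)

    def test_rotated_ellipse_parameters_recovered(self):
        e = fit_ellipse(ellipse_points((120, 80), 20, 10, 30))
        assert e.center[0] == pytest.approx(120, rel=1e-6)
        assert e.center[1] == pytest.approx(80, rel=1e-6)
        assert e.semi_major == pytest.approx(20, rel=1e-6)
        assert e.semi_minor == pytest.approx(10, rel=1e-6)
        assert e.orientation_deg == pytest.approx(30, abs=1e-4)
        assert e.residual_rms < 1e-5

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            fit_ellipse([(0, 0), (1, 0), (1, 1), (0, 1)])

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(10.0), 2.0 * np.arange(10.0)])
        with pytest.raises(DegenerateGeometryError):
            fit_ellipse(pts)

    def test_orientation_normalised(self):
        e = fit_ellipse(ellipse_points((0, 0), 20, 10, 150))
        assert 0 <= e.orientation_deg < 180


class TestScanCortex:
    def test_sample_count_and_spacing(self, bilateral_scene):
        ellipse = fit_ellipse(bilateral_scene.contour)
        profile = scan_cortex(
            bilateral_scene.channels["cortex"], ellipse, bilateral_scene.plate_axis_deg
        )
        assert profile.n_positions == 180
        assert profile.spacing_deg == 2.0
        assert np.array_equal(profile.positions_deg, np.arange(180) * 2.0)

    def test_circumferential_scene_flat_profile(self, noise_free_scenes):
        scene = noise_free_scenes["circumferential"]
        ellipse = fit_ellipse(scene.contour)
        profile = scan_cortex(scene.channels["cortex"], ellipse, scene.plate_axis_deg)
        i = profile.intensities
        assert (i.max() - i.min()) < 0.01 * i.mean()

    def test_bilateral_crescents_peak_at_lateral_positions(self, bilateral_scene):
        ellipse = fit_ellipse(bilateral_scene.contour)
        profile = scan_cortex(
            bilateral_scene.channels["cortex"], ellipse, bilateral_scene.plate_axis_deg
        )
        i = profile.intensities
        # peak within each half must sit at 90 and 270, +/- one 2-deg sample
        k1 = np.argmax(i[:90])
        k2 = 90 + np.argmax(i[90:])
        assert abs(k1 * 2 - 90) <= 2
        assert abs(k2 * 2 - 270) <= 2

    def test_probe_pixel_captured_iff_within_radial_segment(self):
        # bright pixel at radial offset d from the boundary of a centred
        # circle: the position facing the probe reports it iff |d| <= 15,
        # i.e. the pixel lies on the 30-px segment centred on the boundary
        for d, expected in [(0, True), (15, True), (-15, True), (16, False), (-16, False)]:
            img = np.zeros((129, 129))
            img[64, 64 + 30 + d] = 100.0
            circle = FittedEllipse((64.0, 64.0), 30.0, 30.0, 0.0)
            profile = scan_cortex(img, circle, 0.0)
            assert (profile.intensities[0] > 0) == expected, f"offset {d}"

    def test_out_of_bounds_segment_names_position(self):
        img = np.zeros((64, 64))
        circle = FittedEllipse((32.0, 32.0), 28.0, 28.0, 0.0)
        with pytest.raises(OutOfBoundsError, match="position"):
            scan_cortex(img, circle, 0.0)

    def test_mirror_symmetry_reverses_profile(self):
        # an asymmetric (unilateral, off-axis crescent) scene reflected across
        # the reference axis gives the reversed profile
        truth = synthgen.SceneTruth(pattern="unilateral", crescent_center_deg=37.0, seed=3)
        scene = synthgen.make_metaphase_cell(truth, plate_axis_deg=0.0)
        img = scene.channels["cortex"]
        ellipse = fit_ellipse(scene.contour)
        p = scan_cortex(img, ellipse, 0.0).intensities
        p_flip = scan_cortex(img[::-1], ellipse, 0.0).intensities  # reflect about y centre
        reversed_p = np.concatenate([[p[0]], p[1:][::-1]])
        np.testing.assert_allclose(p_flip, reversed_p, atol=1e-6 * p.max())

    def test_rotational_equivariance_of_generator_and_scan(self):
        # the same truth rendered at two plate orientations gives the same
        # profile up to interpolation error
        truth = synthgen.SceneTruth(pattern="bilateral", seed=11)
        profiles = []
        for axis in (90.0, 127.0):
            scene = synthgen.make_metaphase_cell(
                truth, semi_major_px=100.0, semi_minor_px=100.0, plate_axis_deg=axis
            )
            ellipse = fit_ellipse(scene.contour)
            profiles.append(
                scan_cortex(scene.channels["cortex"], ellipse, axis).intensities
            )
        dyn = profiles[0].max() - profiles[0].min()
        np.testing.assert_allclose(profiles[0], profiles[1], atol=0.01 * dyn)


class TestBackground:
    def test_zero_background_is_identity(self, bilateral_scene):
        ellipse = fit_ellipse(bilateral_scene.contour)
        profile = scan_cortex(
            bilateral_scene.channels["cortex"], ellipse, bilateral_scene.plate_axis_deg
        )
        out = subtract_background(profile, 0.0)
        np.testing.assert_array_equal(out.intensities, profile.intensities)

    def test_constant_shift_and_floor(self):
        prof = CorticalProfile(np.arange(180) * 2.0, np.full(180, 100.0))
        assert subtract_background(prof, 40.0).intensities[0] == 60.0
        low = CorticalProfile(np.arange(180) * 2.0, np.full(180, 10.0))
        assert subtract_background(low, 40.0).intensities.min() == 0.0

    def test_background_recorded_and_accumulated(self):
        prof = CorticalProfile(np.arange(180) * 2.0, np.full(180, 100.0))
        out = subtract_background(subtract_background(prof, 10.0), 5.0)
        assert out.background == 15.0

    def test_negative_background_rejected(self):
        prof = CorticalProfile(np.arange(180) * 2.0, np.full(180, 100.0))
        with pytest.raises(ValueError):
            subtract_background(prof, -1.0)


def _profile(values, reference="metaphase_plate"):
    values = np.asarray(values, dtype=float)
    return CorticalProfile(np.arange(len(values)) * 360.0 / len(values), values, reference=reference)


class TestAverageProfiles:
    def test_identical_profiles_mean_equals_input_sem_zero(self):
        p = _profile(np.linspace(0, 100, 180))
        avg = average_profiles([p, p, p])
        np.testing.assert_allclose(avg.mean, p.intensities, rtol=1e-14)
        np.testing.assert_allclose(avg.sem, 0.0, atol=1e-12)
        assert avg.n_cells == 3

    def test_two_profile_closed_form(self):
        avg = average_profiles([_profile(np.zeros(180)), _profile(np.full(180, 2.0))])
        np.testing.assert_array_equal(avg.mean, 1.0)
        np.testing.assert_array_equal(avg.sem, 1.0)

    def test_matches_brute_force_recomputation(self, rng):
        profiles = [_profile(rng.uniform(0, 1000, 180)) for _ in range(20)]
        avg = average_profiles(profiles)
        for k in range(180):
            vals = [p.intensities[k] for p in profiles]
            m = sum(vals) / len(vals)
            sd = np.sqrt(sum((v - m) ** 2 for v in vals) / (len(vals) - 1))
            assert avg.mean[k] == pytest.approx(m, abs=1e-9)
            assert avg.sem[k] == pytest.approx(sd / np.sqrt(len(vals)), abs=1e-9)

    def test_single_profile_rejected(self):
        with pytest.raises(ValueError):
            average_profiles([_profile(np.zeros(180))])

    def test_mixed_reference_conventions_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            average_profiles(
                [_profile(np.zeros(180)), _profile(np.zeros(180), reference="short_axis")]
            )


class TestClassification:
    def test_zero_profile_is_absent(self):
        call = classify_localisation(_profile(np.zeros(180)), noise_floor=0.0)
        assert call.category == "absent"

    @pytest.mark.parametrize("pattern", synthgen.PATTERNS)
    def test_noise_free_patterns_recovered(self, noise_free_scenes, pattern):
        assert classify_scene(noise_free_scenes[pattern]).category == pattern

    def test_scores_exposed_and_finite(self, noise_free_scenes):
        call = classify_scene(noise_free_scenes["bilateral"])
        assert {"lateral_mean", "central_mean", "cv", "noise_floor"} <= set(call.scores)
        assert all(np.isfinite(v) for v in call.scores.values())


class TestTabulateCategories:
    def test_single_category_is_100_percent(self):
        calls = ["bilateral"] * 10
        table = tabulate_categories(calls, ["ctrl"] * 10)
        assert table.loc["ctrl", "bilateral"] == 100.0
        assert table.loc["ctrl"].sum() == 100.0

    def test_three_to_one_split(self):
        table = tabulate_categories(
            ["bilateral"] * 3 + ["central"], ["g"] * 4
        )
        assert table.loc["g", "bilateral"] == 75.0
        assert table.loc["g", "central"] == 25.0

    def test_random_assignment_matches_hand_count(self, rng):
        cats = list(rng.choice(cortex_profile.CATEGORIES, size=60))
        groups = list(rng.choice(["a", "b"], size=60))
        table = tabulate_categories(cats, groups)
        for g in ("a", "b"):
            members = [c for c, gg in zip(cats, groups) if gg == g]
            for cat in cortex_profile.CATEGORIES:
                expected = 100.0 * members.count(cat) / len(members)
                assert table.loc[g, cat] == pytest.approx(expected)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            tabulate_categories([], [])
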