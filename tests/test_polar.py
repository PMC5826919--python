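"""Polar transform, angular profiles, the CV statistic and group tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coccoloc import (
    AngularProfile,
    EstimationError,
    GeometryError,
    ImagingSpec,
    StatisticError,
    angular_profile,
    cell_cv,
    cv_factor,
    cv_group_compare,
    cytoplasm_removal_radius,
    measure_cell_radius,
    polar_transform,
    render_cell,
    significance_stars,
)
from coccoloc.polar import CVResult

from helpers import make_punctate_spec, make_ring_spec


def profile_from(values):
    values = np.asarray(values, dtype=float)
    angles = 2 * math.pi * np.arange(values.size) / values.size
    return AngularProfile(angles=angles, intensities=values, n_radial_samples=1)


class TestPolarTransform:
    def test_constant_image_maps_to_constant(self):
        img = np.full((41, 41), 7.5)
        polar = polar_transform(img, (20, 20), 15, n_angle_bins=36)
        assert np.allclose(polar, 7.5)

    def test_out_of_bounds_radius_rejected(self):
        with pytest.raises(GeometryError):
            polar_transform(np.zeros((41, 41)), (20, 20), 25)

    def test_bright_pixel_lands_in_nearest_bin(self):
        """A single bright pixel appears at the (angle, radius) sample closest
        to its true polar coordinates — checked against brute-force search."""
        img = np.zeros((41, 41))
        px, py = 28, 26  # angle atan2(6, 8), radius 10
        img[py, px] = 100.0
        n_angle, max_r, n_rad = 72, 15, 31
        polar = polar_transform(img, (20, 20), max_r, n_angle_bins=n_angle, n_radial_samples=n_rad)
        i_max, j_max = np.unravel_index(np.argmax(polar), polar.shape)
        # brute force: which sample point is nearest to the bright pixel?
        theta = 2 * math.pi * np.arange(n_angle) / n_angle
        r = max_r * np.arange(n_rad) / (n_rad - 1)
        xs = 20 + r[None, :] * np.cos(theta)[:, None]
        ys = 20 + r[None, :] * np.sin(theta)[:, None]
        d2 = (xs - px) ** 2 + (ys - py) ** 2
        assert (i_max, j_max) == np.unravel_index(np.argmin(d2), d2.shape)

    def test_quarter_turn_rotation_shifts_rows_exactly(self, blur_only_imaging):
        """Rotating the image 90 degrees about the centre cyclically shifts the
        polar image by a quarter of the angle bins (noise-free, < 1e-6)."""
        spec = make_punctate_spec(centre=(24.0, 24.0), angles=(0.3, 1.1, 2.7, 4.0, 5.5), n_puncta=5)
        im = render_cell(spec, blur_only_imaging, 49).blurred
        n_angle = 72
        p0 = polar_transform(im, (24, 24), 12, n_angle_bins=n_angle)
        # rot90 maps (x, y) -> (y, N-1-x): a +90 degree turn in the y-down frame
        p90 = polar_transform(np.rot90(im), (24, 24), 12, n_angle_bins=n_angle)
        assert np.max(np.abs(p90 - np.roll(p0, -n_angle // 4, axis=0))) < 1e-6


class TestAngularProfile:
    def test_uniform_disc_profile_constant(self):
        img = np.full((41, 41), 3.0)
        polar = polar_transform(img, (20, 20), 12, n_angle_bins=36)
        prof = angular_profile(polar, 12)
        assert np.allclose(prof.intensities, 3.0)

    def test_cytoplasm_removal_radius_area_rule(self):
        # central disc of 20% area: r_min = r_max * sqrt(0.2)
        assert cytoplasm_removal_radius(10.0) == pytest.approx(4.4721, abs=1e-3)

    def test_removal_raises_cv_for_cytoplasm_rich_cell(self, blur_only_imaging):
        """Uniform cytoplasmic signal dilutes angular contrast; removing the
        central disc must increase the measured CV of a punctate cell."""
        spec = make_punctate_spec(cytoplasm=0.8)
        im = render_cell(spec, blur_only_imaging, 49).blurred
        cv_with = cell_cv(im, (24, 24), 8, remove_cytoplasm=True).cv
        cv_without = cell_cv(im, (24, 24), 8, remove_cytoplasm=False).cv
        assert cv_with > cv_without

    def test_empty_radial_band_rejected(self):
        polar = np.ones((36, 13))
        with pytest.raises(Exception):
            angular_profile(polar, 12, r_min_px=12, r_max_px=12)


class TestCVFactor:
    def test_constant_profile_gives_zero(self):
        assert cv_factor(profile_from(np.full(360, 5.0))).cv == 0.0

    @pytest.mark.parametrize("a", [0.05, 0.2, 0.5])
    def test_sinusoid_closed_form(self, a):
        """I(theta) = 1 + a*cos(theta): population sd is a/sqrt(2), so
        CV = 100*a/sqrt(2)."""
        theta = 2 * math.pi * np.arange(360) / 360
        res = cv_factor(profile_from(1 + a * np.cos(theta)))
        assert res.cv == pytest.approx(100 * a / math.sqrt(2), rel=0.005)

    def test_two_bin_hand_case(self):
        res = cv_factor(profile_from([1.0, 3.0]))
        assert res.sigma == pytest.approx(1.0)
        assert res.mu == pytest.approx(2.0)
        assert res.cv == pytest.approx(50.0)

    def test_zero_mean_rejected(self):
        with pytest.raises(StatisticError):
            cv_factor(profile_from(np.zeros(10)))

    @settings(deadline=None)
    @given(
        values=st.lists(st.floats(0.1, 1e4), min_size=4, max_size=64),
        scale=st.floats(1e-3, 1e3),
        shift=st.integers(0, 63),
    )
    def test_scale_and_cyclic_shift_invariance(self, values, scale, shift):
        """cv is unchanged by multiplying intensities by c > 0 and by rotating
        the profile (cyclic shift of bins)."""
        base = cv_factor(profile_from(values)).cv
        scaled = cv_factor(profile_from(np.asarray(values) * scale)).cv
        rolled = cv_factor(profile_from(np.roll(values, shift % len(values)))).cv
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)
        assert rolled == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestGroupComparison:
    def test_identical_groups(self):
        g = [CVResult(sigma=1, mu=10, cv=v) for v in (10.0, 12.0, 14.0)]
        res = cv_group_compare(g, list(g))
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)
        assert res.stars == "ns"

    def test_hand_computed_pooled_t(self):
        """{1,2,3} vs {11,12,13}: pooled sd 1, se sqrt(2/3), t = -12.247,
        two-tailed p ~ 2.6e-4 at 4 df."""
        a = [CVResult(0, 1, v) for v in (1.0, 2.0, 3.0)]
        b = [CVResult(0, 1, v) for v in (11.0, 12.0, 13.0)]
        res = cv_group_compare(a, b)
        assert res.t == pytest.approx(-10 / math.sqrt(2 / 3), rel=1e-6)
        assert res.p == pytest.approx(2.56e-4, rel=0.05)
        assert res.stars == "***"

    def test_small_group_rejected(self):
        with pytest.raises(StatisticError):
            cv_group_compare([CVResult(0, 1, 1.0)], [CVResult(0, 1, 2.0), CVResult(0, 1, 3.0)])

    def test_star_thresholds(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.004) == "**"
        assert significance_stars(4e-4) == "***"
        assert significance_stars(4e-5) == "****"
        assert significance_stars(0.2) == "ns"


class TestRadiusAndSizeInvariance:
    def test_ring_radius_recovered(self, blur_only_imaging):
        # cytoplasm-free ring: interior signal would bias the crest inward
        spec = make_ring_spec(centre=(28.0, 28.0), radius=8.0, cytoplasm=0.0)
        im = render_cell(spec, blur_only_imaging, 57).blurred
        assert measure_cell_radius(im, (28, 28)) == pytest.approx(8.0, abs=0.5)

    def test_blank_image_is_estimation_error(self):
        with pytest.raises(EstimationError):
            measure_cell_radius(np.zeros((49, 49)), (24, 24))

    def test_cv_nearly_radius_invariant(self, noise_free_imaging):
        """Same angular pattern at radius 8 vs 12 px: CV differs by < 1 unit
        because the statistic is angular, not geometric.  Holds for the
        unblurred pattern; a fixed-width PSF genuinely narrows angular
        features more on smaller cells."""
        cvs = []
        for radius, size in ((8.0, 57), (12.0, 73)):
            cc = (size - 1) / 2
            spec = make_punctate_spec(centre=(cc, cc), radius=radius,
                                      angles=(0.5, 1.5, 2.6, 3.7, 4.8, 5.9))
            im = render_cell(spec, noise_free_imaging, size).ideal
            cvs.append(cell_cv(im, (cc, cc), radius, remove_cytoplasm=True).cv)
        assert abs(cvs[0] - cvs[1]) < 1.0

    def test_cv_monotone_in_puncta_contrast(self, blur_only_imaging):
        cvs = []
        for contrast in (1.5, 2.0, 3.0, 5.0):
            spec = make_punctate_spec(contrast=contrast, angles=(0.5, 1.5, 2.6, 3.7, 4.8, 5.9))
            im = render_cell(spec, blur_only_imaging, 49).blurred
            cvs.append(cell_cv(im, (24, 24), 8, remove_cytoplasm=True).cv)
        assert np.all(np.diff(cvs) > 0)
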