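import numpy as np
import pytest

from colonychannels import (
    Calibration,
    Image2D,
    ZStack,
    base_area,
    biofilm_thickness,
    estimate_centre,
    max_full_circumference_radius,
    segment_colony,
)
from colonychannels.segmentation import Centre, ColonyMask
from conftest import disk_image


class TestSegmentColony:
    def test_zero_variance_image_rejected(self, calibration):
        with pytest.raises(ValueError, match="no colony"):
            segment_colony(Image2D(np.full((32, 32), 50.0), calibration))

    def test_disk_on_dark_background_recovered_exactly(self, calibration):
        # disk covers ~25% of the frame at value 100: mean ~25, and every
        # disk pixel (100) clears the threshold while background (0) does not
        img = disk_image(100, 28.2)
        mask = segment_colony(Image2D(img, calibration))
        np.testing.assert_array_equal(mask.mask, img >= img.mean())

    def test_largest_component_wins(self, calibration):
        img = disk_image(120, 30, centre=(35.0, 35.0))
        img += disk_image(120, 15, centre=(95.0, 95.0))
        mask = segment_colony(Image2D(img, calibration))
        # only the large disk survives
        assert mask.mask[35, 35] and not mask.mask[95, 95]

    def test_holes_are_filled(self, calibration):
        img = disk_image(64, 20)
        img[30:34, 30:34] = 0.0  # dark hole inside the colony
        mask = segment_colony(Image2D(img, calibration))
        assert mask.mask[31, 31]


class TestBaseArea:
    def test_pixel_count_times_pixel_area(self, calibration):
        m = np.zeros((32, 32), dtype=bool)
        m[:10, :10] = True
        assert base_area(ColonyMask(m, calibration)) == pytest.approx(
            100 * 0.5 * 0.5
        )

    def test_disk_area_matches_analytic_circle(self, calibration):
        img = disk_image(256, 100.0)
        mask = ColonyMask(img > 0, calibration)
        analytic = np.pi * (100 * 0.5) ** 2
        assert base_area(mask) == pytest.approx(analytic, rel=0.02)

    def test_full_frame_mask_exact(self, calibration):
        m = np.ones((40, 50), dtype=bool)
        assert base_area(ColonyMask(m, calibration)) == 40 * 50 * 0.25

    def test_rotation_invariance(self, calibration):
        rng = np.random.default_rng(0)
        m = rng.random((33, 47)) > 0.6
        m[0, 0] = True
        a1 = base_area(ColonyMask(m, calibration))
        a2 = base_area(ColonyMask(np.rot90(m), calibration))
        assert a1 == a2


class TestEstimateCentre:
    def test_centred_disk(self, calibration):
        mask = ColonyMask(disk_image(101, 30) > 0, calibration)
        c = estimate_centre(mask)
        assert abs(c.x_px - 50.0) < 0.5 and abs(c.y_px - 50.0) < 0.5

    def test_translation_equivariance(self, calibration):
        base = disk_image(120, 25, centre=(50.0, 48.0)) > 0
        moved = np.roll(np.roll(base, 13, axis=0), -7, axis=1)
        c0 = estimate_centre(ColonyMask(base, calibration))
        c1 = estimate_centre(ColonyMask(moved, calibration))
        assert c1.x_px - c0.x_px == pytest.approx(-7, abs=1e-9)
        assert c1.y_px - c0.y_px == pytest.approx(13, abs=1e-9)

    def test_ellipse_centroid_is_ellipse_centre(self, calibration):
        ys, xs = np.mgrid[0:90, 0:110]
        m = ((xs - 60) / 40.0) ** 2 + ((ys - 44) / 25.0) ** 2 <= 1
        c = estimate_centre(ColonyMask(m, calibration))
        assert c.x_px == pytest.approx(60, abs=0.1)
        assert c.y_px == pytest.approx(44, abs=0.1)


class TestMaxFullCircumferenceRadius:
    def test_centred_disk_radius(self, calibration):
        mask = ColonyMask(disk_image(201, 80) > 0, calibration)
        r = max_full_circumference_radius(mask, Centre(100.0, 100.0))
        assert r == pytest.approx(80 * 0.5, abs=1.0 * 0.5)

    @pytest.mark.parametrize("d", [10, 25, 40])
    def test_offset_centre_loses_offset(self, calibration, d):
        mask = ColonyMask(disk_image(201, 80) > 0, calibration)
        r = max_full_circumference_radius(mask, Centre(100.0 + d, 100.0))
        assert r == pytest.approx((80 - d) * 0.5, abs=1.5 * 0.5)

    def test_centre_on_mask_border_gives_zero(self, calibration):
        mask = ColonyMask(disk_image(201, 80) > 0, calibration)
        assert max_full_circumference_radius(mask, Centre(180.0, 100.0)) == 0.0

    def test_centre_outside_mask_rejected(self, calibration):
        mask = ColonyMask(disk_image(201, 80) > 0, calibration)
        with pytest.raises(ValueError, match="outside"):
            max_full_circumference_radius(mask, Centre(5.0, 5.0))

    def test_bounded_by_centroid_to_boundary_distance(self, calibration):
        rng = np.random.default_rng(5)
        m = disk_image(101, 30) > 0
        mask = ColonyMask(m, calibration)
        c = estimate_centre(mask)
        r = max_full_circumference_radius(mask, c)
        ys, xs = np.nonzero(m)
        max_dist = np.hypot(xs - c.x_px, ys - c.y_px).max() * 0.5
        assert r <= max_dist + 0.5


class TestBiofilmThickness:
    def _stack_from_profile(self, profile, z_step=3.0):
        cal = Calibration(pixel_size_um=1.0, z_step_um=z_step)
        return ZStack(
            [Image2D(np.full((16, 16), float(v)), cal) for v in profile]
        )

    def test_two_end_minima_span_full_depth(self):
        z = np.arange(71)
        profile = 20.0 - 10.0 * np.cos(2 * np.pi * z / 70.0)  # minima at 0 and 70
        stack = self._stack_from_profile(profile, z_step=3.0)
        assert biofilm_thickness(stack) == pytest.approx(70 * 3.0)

    def test_interior_minima_distance(self):
        z = np.arange(40)
        profile = 50.0 + 20.0 * np.cos(2 * np.pi * (z - 5) / 30.0)
        # minima of cos at z = 20; craft two dips explicitly instead
        profile = np.full(40, 50.0)
        profile[8] = 10.0
        profile[31] = 12.0
        stack = self._stack_from_profile(profile, z_step=2.0)
        assert biofilm_thickness(stack, smooth=False) == pytest.approx((31 - 8) * 2.0)

    def test_monotone_profile_has_no_thickness(self):
        stack = self._stack_from_profile(np.linspace(10, 100, 30))
        with pytest.raises(ValueError, match="thickness undefined"):
            biofilm_thickness(stack)

    def test_requires_z_calibration(self):
        cal = Calibration(pixel_size_um=1.0)
        stack = ZStack([Image2D(np.full((16, 16), v), cal) for v in (5.0, 1.0, 5.0)])
        with pytest.raises(ValueError, match="z_step"):
            biofilm_thickness(stack)
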