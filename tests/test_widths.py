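import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal

from colonychannels import (
    Profile,
    detect_peaks,
    extract_profile,
    modified_z_scores,
    peak_fwhm,
    remove_outliers,
    widths_to_um,
)
from colonychannels.widths import circular_prominence
from conftest import make_polar
from oracles import brute_detect_peaks, brute_remove_outliers


def profile_with_gaussian_peak(n=200, centre=100, sigma=3.0, height=100.0):
    x = np.arange(n)
    return height * np.exp(-((x - centre) ** 2) / (2 * sigma**2))


class TestExtractProfile:
    def test_uniform_polar_gives_constant_profile(self):
        p = make_polar(np.full((50, 360), 80.0))
        prof = extract_profile(p, 20.0)
        assert np.allclose(prof.values, 80.0)
        assert prof.radius_um == 20.0

    def test_row_snapping_uses_pixel_size(self):
        a = np.zeros((50, 360))
        a[30] = 99.0
        p = make_polar(a, pixel_size_um=2.0)
        prof = extract_profile(p, 60.4)  # nearest row = 30
        assert np.allclose(prof.values, 99.0)

    def test_incomplete_circumference_rejected(self):
        valid = np.ones((50, 360), bool)
        valid[40, 100] = False
        p = make_polar(np.zeros((50, 360)), valid=valid)
        with pytest.raises(ValueError, match="incomplete circumference"):
            extract_profile(p, 40.0)

    def test_radius_beyond_raster_rejected(self):
        p = make_polar(np.zeros((50, 360)))
        with pytest.raises(ValueError, match="incomplete circumference"):
            extract_profile(p, 80.0)


class TestDetectPeaks:
    def test_flat_profile_has_no_peaks(self):
        assert detect_peaks(np.full(100, 5.0)) == []

    def test_single_triangular_peak(self):
        x = np.zeros(100)
        x[45:56] = [0, 20, 40, 60, 80, 100, 80, 60, 40, 20, 0]
        assert detect_peaks(x) == [50]

    def test_distance_rule_keeps_higher_of_close_pair(self):
        x = np.zeros(100)
        x[30] = 100.0
        x[35] = 80.0  # 5 px away, closer than the 9 px minimum
        assert detect_peaks(x) == [30]

    def test_peak_spanning_the_angular_seam(self):
        x = np.zeros(120)
        x[-2:] = [50, 90]
        x[:3] = [100, 70, 30]
        peaks = detect_peaks(x)
        assert peaks == [0]

    def test_prominence_threshold_is_relative_to_range(self):
        x = np.zeros(100)
        x[20] = 100.0
        x[60] = 15.0  # prominence 15 < 20% of range
        assert detect_peaks(x) == [20]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_profiles(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 120))
        x = rng.random(n) * 100
        if seed % 2:
            x = np.round(x / 10) * 10  # integer-ish values with plateaus
        assert detect_peaks(x) == brute_detect_peaks(x)

    def test_agrees_with_scipy_on_interior_peaks(self):
        # independent cross-check in the non-wrapped regime: a profile whose
        # ends are the global minimum, so circularity cannot matter
        rng = np.random.default_rng(42)
        x = np.concatenate([[0.0], rng.random(200) * 100 + 10, [0.0]])
        ours = detect_peaks(x, prominence_fraction=0.2, min_distance_px=9)
        rng_range = x.max() - x.min()
        theirs, _ = signal.find_peaks(x, prominence=0.2 * rng_range, distance=9)
        assert ours == sorted(theirs)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(15)
        x = rng.random(90) * 50
        base = detect_peaks(x)
        shifted = detect_peaks(np.roll(x, 17))
        assert sorted((p + 17) % 90 for p in base) == shifted


class TestPeakFwhm:
    def test_symmetric_triangle_half_base(self):
        x = np.zeros(60)
        x[20:31] = [0, 20, 40, 60, 80, 100, 80, 60, 40, 20, 0]
        assert peak_fwhm(x, 25) == pytest.approx(5.0)

    def test_gaussian_closed_form(self):
        x = profile_with_gaussian_peak(sigma=3.0)
        fwhm = peak_fwhm(x, 100)
        assert fwhm == pytest.approx(2 * np.sqrt(2 * np.log(2)) * 3.0, rel=0.03)

    def test_rectangular_pulse(self):
        x = np.zeros(50)
        x[10:14] = 100.0
        peaks = detect_peaks(x)
        assert len(peaks) == 1
        assert peak_fwhm(x, peaks[0]) == pytest.approx(4.0)

    def test_wrapped_peak_width(self):
        x = np.zeros(100)
        x[-2:] = [50.0, 80.0]
        x[:3] = [100.0, 80.0, 50.0]
        peaks = detect_peaks(x)
        sym = np.zeros(100)
        sym[48:53] = [50.0, 80.0, 100.0, 80.0, 50.0]
        assert peak_fwhm(x, peaks[0]) == pytest.approx(peak_fwhm(sym, 50))

    def test_prominence_referenced_level_ignores_baseline(self):
        # the same peak on a raised baseline must keep its width
        x0 = profile_with_gaussian_peak(sigma=4.0)
        x1 = x0 + 40.0
        assert peak_fwhm(x1, 100) == pytest.approx(peak_fwhm(x0, 100), rel=1e-6)


class TestWidthsToUm:
    def test_zero_width(self):
        p = make_polar(np.zeros((10, 7200)))
        (det,) = widths_to_um([(200.0, 0.0, 0.0, 1.0)], p)
        assert det.width_um == 0.0

    def test_worked_arc_conversion(self):
        p = make_polar(np.zeros((10, 7200)))
        (det,) = widths_to_um([(200.0, 10.0, 20.0, 1.0)], p)
        assert det.width_um == pytest.approx(3.49065, abs=1e-4)

    def test_linear_in_radius(self):
        p = make_polar(np.zeros((10, 7200)))
        d1, d2 = widths_to_um(
            [(100.0, 0.0, 15.0, 1.0), (200.0, 0.0, 15.0, 1.0)], p
        )
        assert d2.width_um == pytest.approx(2 * d1.width_um)


class TestRemoveOutliers:
    def test_constant_values_all_retained(self):
        assert remove_outliers([5.0, 5.0, 5.0, 5.0]) == [5.0] * 4

    def test_single_gross_outlier_removed(self):
        assert remove_outliers([1, 2, 3, 4, 100]) == [1, 2, 3, 4]
        scores = modified_z_scores([1, 2, 3, 4, 100])
        assert scores[-1] == pytest.approx(0.6745 * 97, rel=1e-9)

    def test_threshold_is_strict(self):
        x = [1.0, 2.0, 3.0, 4.0, 100.0]
        at_limit = abs(modified_z_scores(x)[-1])
        # a point whose score equals the threshold exactly is retained
        assert remove_outliers(x, threshold=at_limit) == x

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            remove_outliers([])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.lognormal(2.0, 0.4, size=rng.integers(1, 40))
        if seed % 3 == 0:
            x = np.round(x)  # provoke MAD = 0 fallbacks via duplicates
        assert remove_outliers(x) == brute_remove_outliers(x)

    def test_second_pass_removes_nothing_after_gross_outlier(self):
        kept = remove_outliers([1, 2, 3, 4, 100])
        assert remove_outliers(kept) == kept


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_peak_count_bounded_by_distance_rule(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(20, 150))
    x = rng.random(n) * 100
    d = int(rng.integers(1, max(2, n // 4)))
    peaks = detect_peaks(x, prominence_fraction=0.0, min_distance_px=d)
    assert len(peaks) <= n // d


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_prominence_never_exceeds_range(seed):
    rng = np.random.default_rng(seed)
    x = rng.random(60) * 100
    for p in detect_peaks(x, prominence_fraction=0.0, min_distance_px=1):
        prom = circular_prominence(x, p)
        assert 0.0 <= prom <= np.ptp(x) + 1e-12
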