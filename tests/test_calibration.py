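"""Calibration pipeline: pixel statistics, the three linear fits, flatfield,
derived maps and the traditional light-level comparison method."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import least_squares

import darkcal as dc
from darkcal.calibration import (
    CalibrationError,
    PixelStats,
    RunningStats,
    _ols_lines,
)
from darkcal.experiments import analytic_pixel_stats, simulate_pixel_stats


def make_stats(times, means, variances, n_frames=100):
    times = np.asarray(times, dtype=float)
    means = np.asarray(means, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if means.ndim == 1:  # scalar per time -> 1x1 maps
        means = means[:, None, None]
        variances = variances[:, None, None]
    return PixelStats(times, means, variances, np.full(times.size, n_frames))


class TestPixelStatistics:
    def test_hand_computed_mean_and_variance(self):
        frames = np.array([[[10]], [[12]]], dtype=np.uint16)
        series = dc.ExposureSeries((0.1, 0.2, 0.3), [frames, frames, frames])
        stats = dc.pixel_statistics(series)
        assert stats.means[0, 0, 0] == 11.0
        assert stats.variances[0, 0, 0] == 2.0  # (1^2 + 1^2) / (2 - 1)

    def test_identical_frames_have_zero_variance(self):
        frames = np.full((5, 3, 3), 7, dtype=np.uint16)
        series = dc.ExposureSeries((0.1, 0.2, 0.3), [frames] * 3)
        stats = dc.pixel_statistics(series)
        assert np.all(stats.variances == 0)

    def test_streaming_matches_in_memory_oracle(self):
        rng = np.random.default_rng(0)
        stack = rng.integers(90, 130, size=(100, 8, 8)).astype(np.uint16)

        def chunks():
            for i in range(0, 100, 7):
                yield stack[i : i + 7]

        rs = RunningStats()
        for c in chunks():
            rs.update(c)
        np.testing.assert_allclose(rs.mean(), stack.mean(axis=0), rtol=1e-9)
        np.testing.assert_allclose(rs.variance(), stack.var(axis=0, ddof=1), rtol=1e-9)

    def test_mismatched_shapes_rejected(self):
        good = np.zeros((4, 3, 3), dtype=np.uint16)
        bad = np.zeros((4, 2, 2), dtype=np.uint16)
        series = dc.ExposureSeries((0.1, 0.2, 0.3), [good, good, good])
        series.frames[2] = [bad[i] for i in range(4)]  # sneak past validation
        with pytest.raises((ValueError, CalibrationError)):
            dc.pixel_statistics(series)


class TestLinearFits:
    def test_collinear_mean_fit_is_exact(self):
        stats = make_stats([0.0, 0.1, 0.5], [100.0, 105.0, 125.0], [1.0, 1.0, 1.0])
        baseline, slope, r2 = dc.fit_mean_vs_time(stats)
        assert baseline[0, 0] == pytest.approx(100.0, abs=1e-9)
        assert slope[0, 0] == pytest.approx(50.0, abs=1e-9)
        assert r2[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_collinear_variance_fit_is_exact(self):
        stats = make_stats([0.0, 0.1, 0.5], [100.0, 105.0, 125.0], [4.0, 9.0, 29.0])
        rn_sq, tn_sq, _ = dc.fit_variance_vs_time(stats)
        assert rn_sq[0, 0] == pytest.approx(4.0, abs=1e-9)
        assert tn_sq[0, 0] == pytest.approx(50.0, abs=1e-9)

    def test_degenerate_design_rejected(self):
        stats = make_stats([0.1, 0.1, 0.1], [1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        with pytest.raises(CalibrationError):
            dc.fit_mean_vs_time(stats)
        with pytest.raises(CalibrationError):
            dc.fit_mean_vs_time(make_stats([0.1, 0.2], [1.0, 2.0], [1.0, 1.0]))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.data())
    def test_closed_form_equals_iterative_least_squares(self, data):
        """The vectorized closed-form OLS must agree with an independent
        iterative least-squares solver to 1e-9 relative."""
        n = data.draw(st.integers(3, 7))
        # well-spaced design points keep both solvers well-conditioned
        x = np.array(
            data.draw(
                st.lists(st.integers(0, 100), min_size=n, max_size=n, unique=True)
            ),
            dtype=float,
        ) / 100.0
        y = np.array(
            data.draw(
                st.lists(st.floats(-100.0, 100.0), min_size=n, max_size=n)
            )
        )
        intercept, slope, _ = _ols_lines(x, y[:, None, None])

        def resid(p):
            return p[0] + p[1] * x - y

        def jac(p):
            return np.column_stack([np.ones_like(x), x])

        fit = least_squares(
            resid, x0=[0.0, 0.0], jac=jac, method="lm",
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        scale = max(1.0, abs(fit.x[0]), abs(fit.x[1]))
        assert abs(intercept[0, 0] - fit.x[0]) < 1e-9 * scale
        assert abs(slope[0, 0] - fit.x[1]) < 1e-9 * scale

    def test_gain_fit_recovers_uniform_gain_exactly_in_the_limit(self):
        """On analytic (infinite-frame) statistics the variance-vs-mean slope
        is the gain with no error: var = g^2 RN^2 + g (mean - BL)."""
        gt = dc.make_synthetic_camera(
            (12, 12), hot_pixel_fraction=0.0, seed=11,
            parameter_ranges={"gain": (2.2, 1e-12)},
        )
        stats = analytic_pixel_stats(gt, [0.001, 0.05, 0.2, 0.5])
        gain, r2 = dc.fit_variance_vs_mean(stats)
        np.testing.assert_allclose(gain, 2.2, rtol=1e-9)
        np.testing.assert_allclose(r2, 1.0, atol=1e-12)

    def test_zero_dark_current_pixel_flagged_missing(self):
        gt = dc.make_synthetic_camera((6, 6), hot_pixel_fraction=0.0, seed=12)
        dcm = gt.dark_current.copy()
        dcm[2, 3] = 0.0
        gt = replace(gt, dark_current=dcm)
        stats = analytic_pixel_stats(gt, [0.001, 0.05, 0.2, 0.5])
        gain, _ = dc.fit_variance_vs_mean(stats)
        assert np.isnan(gain[2, 3])
        assert np.isfinite(dc.aggregate_gain(gain))


class TestAggregateGain:
    def test_median_is_robust_to_outlier(self):
        assert dc.aggregate_gain(np.array([1.0, 2.0, 100.0])) == 2.0

    def test_all_equal(self):
        assert dc.aggregate_gain(np.full((4, 4), 1.7)) == pytest.approx(1.7)

    def test_all_missing_raises(self):
        with pytest.raises(CalibrationError):
            dc.aggregate_gain(np.full((3, 3), np.nan))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.1, 10.0), min_size=1, max_size=50))
    def test_matches_sort_based_oracle(self, values):
        arr = np.array(values)
        srt = np.sort(arr)
        n = srt.size
        oracle = srt[n // 2] if n % 2 else 0.5 * (srt[n // 2 - 1] + srt[n // 2])
        assert dc.aggregate_gain(arr) == pytest.approx(oracle, rel=1e-12)


class TestFlatfield:
    def test_uniform_bright_frame_gives_unit_map(self):
        offset = np.full((32, 32), 100.0)
        bright = offset + 2000.0
        flat = dc.flatfield_from_bright(bright, offset)
        np.testing.assert_allclose(flat, 1.0, atol=1e-9)

    def test_high_sensitivity_pixel_detected(self):
        offset = np.full((32, 32), 100.0)
        signal = np.full((32, 32), 2000.0)
        signal[10, 20] *= 1.10
        flat = dc.flatfield_from_bright(offset + signal, offset)
        assert flat[10, 20] == pytest.approx(1.10, abs=0.005)

    def test_illumination_gradient_absorbed(self):
        """A smooth 2x illumination gradient must not leak into the
        sensitivity map (interior pixels; smoothing has edge effects)."""
        offset = np.full((32, 32), 100.0)
        profile = 1.0 + np.linspace(0.0, 1.0, 32)[None, :]
        bright = offset + 2000.0 * profile
        flat = dc.flatfield_from_bright(bright, offset)
        assert np.allclose(flat[8:-8, 8:-8], 1.0, atol=0.02)

    def test_dim_frame_rejected(self):
        offset = np.full((16, 16), 100.0)
        with pytest.raises(CalibrationError):
            dc.flatfield_from_bright(offset + 50.0, offset)

    def test_saturated_frame_rejected(self):
        offset = np.full((16, 16), 100.0)
        bright = np.full((16, 16), 65535.0)
        with pytest.raises(CalibrationError):
            dc.flatfield_from_bright(bright, offset, saturation=65535)


class TestDerivedMaps:
    def test_zero_exposure_returns_intercepts(self, calibration_run):
        _, _, cal = calibration_run
        maps = dc.derive_maps(cal, 0.0)
        np.testing.assert_array_equal(maps.offset, cal.baseline)
        np.testing.assert_array_equal(
            maps.variance, np.maximum(cal.read_noise_sq_adu, 0.0)
        )

    def test_offset_monotone_in_exposure(self, calibration_run):
        _, _, cal = calibration_run
        m1 = dc.derive_maps(cal, 0.05)
        m2 = dc.derive_maps(cal, 0.30)
        pos = cal.dark_current_adu >= 0
        assert np.all((m2.offset - m1.offset)[pos] >= 0)

    def test_negative_intercepts_floored_only_here(self):
        cal = dc.CalibrationResult(
            baseline=np.array([[100.0]]),
            dark_current_adu=np.array([[10.0]]),
            read_noise_sq_adu=np.array([[-0.5]]),
            thermal_noise_sq_adu=np.array([[20.0]]),
            gain=np.array([[2.0]]),
            median_gain=2.0,
            flatfield=np.array([[1.0]]),
        )
        assert cal.read_noise_sq_adu[0, 0] == -0.5  # retained in the result
        assert dc.derive_maps(cal, 0.0).variance[0, 0] == 0.0
        assert dc.derive_maps(cal, 0.1).variance[0, 0] == pytest.approx(1.5)


class TestCalibrate:
    def test_round_trip_recovers_ground_truth(self, calibration_run):
        gt, stats, cal = calibration_run
        n = stats.n_frames[0]
        assert np.sqrt(np.mean((cal.baseline - gt.baseline) ** 2)) < 0.2
        assert cal.median_gain == pytest.approx(float(np.median(gt.gain)), rel=0.02)
        # dark current in ADU/s against truth
        np.testing.assert_allclose(
            cal.dark_current_adu, gt.gain * gt.dark_current, rtol=0.15
        )
        # electron-domain views consistent with median-gain scaling
        np.testing.assert_allclose(
            cal.dark_current_e, cal.dark_current_adu / cal.median_gain
        )

    def test_thermal_dark_current_consistency(self, calibration_run):
        """TN^2 (slope of variance) over gain*DC (slope of mean x gain) must
        be ~1: the Poisson mean=variance identity across two separate fits."""
        _, _, cal = calibration_run
        ratio = np.median(cal.thermal_noise_sq_adu) / (
            cal.median_gain * np.median(cal.dark_current_adu)
        )
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_no_bright_frame_means_identity_flatfield(self, calibration_run):
        _, _, cal = calibration_run
        assert np.all(cal.flatfield == 1.0)
        maps = dc.derive_maps(cal, 0.1)
        np.testing.assert_allclose(maps.photon_response, cal.median_gain)

    def test_repeatability(self, small_camera, calibration_run):
        _, _, cal1 = calibration_run
        stats2 = simulate_pixel_stats(
            small_camera, (0.001, 0.010, 0.050, 0.100, 0.500), 3000, seed=78
        )
        cal2 = dc.calibrate(stats2)
        assert cal1.median_gain == pytest.approx(cal2.median_gain, rel=0.01)
        assert np.median(cal1.baseline) == pytest.approx(
            np.median(cal2.baseline), abs=0.1
        )

    def test_diagnostics_reported(self, calibration_run):
        _, _, cal = calibration_run
        d = cal.diagnostics
        assert d["median_r2_mean_fit"] > 0.99
        assert d["n_missing_gain"] == 0
        assert len(d["n_frames_per_time"]) == 5


@pytest.fixture(scope="module")
def traditional(small_camera):
    t = 0.010
    levels = (0.0, 300.0, 1000.0, 3000.0)
    stacks = {
        lv: dc.simulate_bright_frames(small_camera, lv, t, 4000, seed=30 + i)
        for i, lv in enumerate(levels)
    }
    return dc.traditional_light_calibration(stacks, t), t


class TestTraditionalCalibration:

    def test_offset_includes_thermal_contribution(self, small_camera, traditional):
        (offset, _, _), t = traditional
        excess = np.mean(offset - small_camera.baseline)
        expected = np.mean(small_camera.gain * small_camera.dark_current) * t
        assert excess == pytest.approx(expected, rel=0.15)

    def test_gain_recovery(self, small_camera, traditional):
        (_, _, gain), _ = traditional
        assert dc.aggregate_gain(gain) == pytest.approx(
            float(np.median(small_camera.gain)), rel=0.02
        )

    def test_degenerate_designs_rejected(self, small_camera):
        stack = dc.simulate_dark_frames(small_camera, 0.01, 5, seed=0)
        with pytest.raises(CalibrationError):
            dc.traditional_light_calibration({0.0: stack, 100.0: stack}, 0.01)
        with pytest.raises(CalibrationError):
            dc.traditional_light_calibration(
                {100.0: stack, 200.0: stack, 300.0: stack}, 0.01
            )
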