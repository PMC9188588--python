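"""Seeded desk-scale validation experiments for the photon-free pipeline.

Three quantitative checks:

* :func:`holdout_map_validation` — calibrate on one set of exposure times,
  predict offset and noise maps at held-out times, and compare against
  freshly simulated dark frames (mean relative error over pixels, then
  averaged over held-out times).
* :func:`gain_method_comparison` — median gain from the photon-free method
  vs. the traditional varying-light-level method on the same camera.
* :func:`thermal_offset_check` — the exposure-time-dependent offset
  increase that a fixed-exposure "traditional" characterization silently
  absorbs into its baseline.

All experiments are reproducible from (configuration, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import camera as cam_mod
from .calibration import (
    CalibrationResult,
    PixelStats,
    aggregate_gain,
    calibrate,
    derive_maps,
    traditional_light_calibration,
)
from .camera import (
    CameraGroundTruth,
    as_seed_sequence,
    dark_frame_stats,
    iter_dark_frames,
    make_synthetic_camera,
)

__all__ = [
    "ValidationReport",
    "standard_fixture",
    "camera_with_mean_dark_current_adu",
    "simulate_pixel_stats",
    "analytic_pixel_stats",
    "holdout_map_validation",
    "gain_method_comparison",
    "thermal_offset_check",
    "STANDARD_CALIB_TIMES_S",
    "STANDARD_HOLDOUT_TIMES_S",
]

#: standard fixture calibration exposure times, seconds (1 ms - 500 ms)
STANDARD_CALIB_TIMES_S: tuple[float, ...] = (0.001, 0.010, 0.050, 0.100, 0.500)
#: held-out exposure times for map validation, seconds
STANDARD_HOLDOUT_TIMES_S: tuple[float, ...] = (0.030, 0.200)


def standard_fixture(shape: tuple[int, int] = (64, 64), seed: int | None = 0) -> CameraGroundTruth:
    """The standard synthetic camera: 64x64 pixels, 1% hot pixels, baseline
    ~100 ADU, read noise ~1.5 e-, log-normal dark current with median
    28 e-/s, gain ~2 ADU/e-, flatfield within 2%."""
    return make_synthetic_camera(shape, hot_pixel_fraction=0.01, seed=seed)


def camera_with_mean_dark_current_adu(
    target_adu_per_s: float,
    shape: tuple[int, int] = (64, 64),
    seed: int | None = 0,
    **kwargs,
) -> CameraGroundTruth:
    """Standard-style camera rescaled so mean(gain * dark_current) hits an
    exact ADU/s rate (useful to pin the expected offset increase at a given
    exposure time, e.g. 56 ADU/s -> 0.56 ADU at 10 ms)."""
    gt = make_synthetic_camera(shape, seed=seed, **kwargs)
    current = float(np.mean(gt.gain * gt.dark_current))
    return replace(gt, dark_current=gt.dark_current * (target_adu_per_s / current))


def simulate_pixel_stats(
    gt: CameraGroundTruth,
    exposure_times: Sequence[float],
    n_per_time: int,
    seed: int | None = None,
) -> PixelStats:
    """Streaming per-pixel statistics of freshly simulated dark series (one
    RNG child stream per exposure time; only one chunk resident at a time)."""
    seq = as_seed_sequence(seed)
    children = seq.spawn(len(exposure_times))
    means, variances = [], []
    for t, child in zip(exposure_times, children):
        m, v = dark_frame_stats(gt, t, n_per_time, seed=child)
        means.append(m)
        variances.append(v)
    return PixelStats(
        exposure_times=np.asarray(exposure_times, dtype=float),
        means=np.stack(means),
        variances=np.stack(variances),
        n_frames=np.full(len(exposure_times), n_per_time),
    )


def analytic_pixel_stats(gt: CameraGroundTruth, exposure_times: Sequence[float]) -> PixelStats:
    """Infinite-frames limit: the model's exact moments instead of sampled
    frames (no sampling noise, no quantization)."""
    times = np.asarray(exposure_times, dtype=float)
    # n_frames ~ infinity: standard errors vanish, no pixel is degenerate
    return PixelStats(
        exposure_times=times,
        means=np.stack([gt.expected_dark_mean(t) for t in times]),
        variances=np.stack([gt.expected_dark_variance(t) for t in times]),
        n_frames=np.full(times.size, 10**12),
    )


@dataclass
class ValidationReport:
    """Serializable record of a validation experiment."""

    seed: int | None = None
    config: dict = field(default_factory=dict)
    per_time: dict = field(default_factory=dict)
    offset_error_pct: float | None = None
    noise_error_pct: float | None = None
    median_gain_photon_free: float | None = None
    median_gain_traditional: float | None = None
    gain_deviation_pct: float | None = None
    true_median_gain: float | None = None

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config": self.config,
            "per_time": self.per_time,
            "offset_error_pct": self.offset_error_pct,
            "noise_error_pct": self.noise_error_pct,
            "median_gain_photon_free": self.median_gain_photon_free,
            "median_gain_traditional": self.median_gain_traditional,
            "gain_deviation_pct": self.gain_deviation_pct,
            "true_median_gain": self.true_median_gain,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def holdout_map_validation(
    camera: CameraGroundTruth,
    calib_times: Sequence[float] = STANDARD_CALIB_TIMES_S,
    holdout_times: Sequence[float] = STANDARD_HOLDOUT_TIMES_S,
    n_frames: int = 8000,
    seed: int | None = 0,
    n_frames_holdout: int | None = None,
    analytic: bool = False,
) -> tuple[ValidationReport, CalibrationResult]:
    """Predict offset/noise maps at held-out exposure times and compare to
    direct measurement.

    Calibrates on ``calib_times``; for each held-out time ``t`` the
    predicted per-pixel offset ``BL + DC_adu*t`` and noise
    ``sqrt(RN^2 + TN^2*t)`` are compared to the per-pixel mean and standard
    deviation of ``n_frames_holdout`` freshly simulated dark frames.  Errors
    are ``mean_pixels(|predicted - measured| / measured) * 100``, averaged
    over pixels first and then over held-out times.  With
    ``analytic=True`` both calibration input and "measurement" use the
    model's exact moments (a self-consistency oracle that must give ~0).
    """
    calib_times = tuple(float(t) for t in calib_times)
    holdout_times = tuple(float(t) for t in holdout_times)
    if set(calib_times) & set(holdout_times):
        raise ValueError("holdout times must be disjoint from calibration times")
    if n_frames_holdout is None:
        n_frames_holdout = n_frames

    seq = as_seed_sequence(seed)
    calib_seed, *holdout_seeds = seq.spawn(1 + len(holdout_times))

    if analytic:
        stats = analytic_pixel_stats(camera, calib_times)
    else:
        stats = simulate_pixel_stats(camera, calib_times, n_frames, seed=calib_seed)
    cal = calibrate(stats, bit_depth=camera.bit_depth)

    per_time: dict = {}
    offset_errors, noise_errors = [], []
    for t, child in zip(holdout_times, holdout_seeds):
        maps = derive_maps(cal, t)
        if analytic:
            meas_mean = camera.expected_dark_mean(t)
            meas_var = camera.expected_dark_variance(t)
        else:
            meas_mean, meas_var = dark_frame_stats(camera, t, n_frames_holdout, seed=child)
        off_err = float(np.mean(np.abs(maps.offset - meas_mean) / meas_mean) * 100.0)
        pred_sd = np.sqrt(maps.variance)
        meas_sd = np.sqrt(meas_var)
        sd_err = float(np.mean(np.abs(pred_sd - meas_sd) / meas_sd) * 100.0)
        offset_errors.append(off_err)
        noise_errors.append(sd_err)
        per_time[f"{t * 1e3:g}ms"] = {"offset_error_pct": off_err, "noise_error_pct": sd_err}

    report = ValidationReport(
        seed=seed,
        config={
            "calib_times_s": list(calib_times),
            "holdout_times_s": list(holdout_times),
            "n_frames": n_frames,
            "n_frames_holdout": n_frames_holdout,
            "camera_shape": list(camera.shape),
            "analytic": analytic,
        },
        per_time=per_time,
        offset_error_pct=float(np.mean(offset_errors)),
        noise_error_pct=float(np.mean(noise_errors)),
    )
    return report, cal


def gain_method_comparison(
    camera: CameraGroundTruth,
    seed: int | None = 0,
    calib_times: Sequence[float] = STANDARD_CALIB_TIMES_S,
    n_frames: int = 8000,
    light_levels: Sequence[float] = (0.0, 200.0, 500.0, 1000.0, 2000.0),
    light_exposure_s: float = 0.010,
    n_frames_light: int = 5000,
    photon_free_cal: CalibrationResult | None = None,
) -> ValidationReport:
    """Median gain: photon-free calibration vs. traditional varying-light
    calibration at a fixed 10 ms exposure, on the same camera.

    Light stacks are simulated lazily (chunked generators), so only one
    chunk is resident at a time.  Reports both medians and their relative
    deviation ``|photon_free - traditional| / traditional * 100``.
    """
    if len(light_levels) < 3 or 0.0 not in {float(l) for l in light_levels}:
        raise ValueError("need >= 3 light levels including darkness (0)")
    seq = as_seed_sequence(seed)
    pf_seed, *light_seeds = seq.spawn(1 + len(light_levels))

    if photon_free_cal is None:
        stats = simulate_pixel_stats(camera, calib_times, n_frames, seed=pf_seed)
        photon_free_cal = calibrate(stats, bit_depth=camera.bit_depth)
    g_pf = photon_free_cal.median_gain

    def light_chunks(level: float, child):
        rng = np.random.default_rng(child)
        rate = camera.flatfield * level + camera.dark_current * light_exposure_s
        done = 0
        while done < n_frames_light:
            k = min(256, n_frames_light - done)
            yield cam_mod._draw_frames(camera, rate, k, rng)
            done += k

    stacks = {
        float(level): light_chunks(float(level), child)
        for level, child in zip(light_levels, light_seeds)
    }
    _, _, gain_map = traditional_light_calibration(stacks, light_exposure_s)
    g_trad = aggregate_gain(gain_map)

    return ValidationReport(
        seed=seed,
        config={
            "calib_times_s": [float(t) for t in calib_times],
            "n_frames": n_frames,
            "light_levels": [float(l) for l in light_levels],
            "light_exposure_s": light_exposure_s,
            "n_frames_light": n_frames_light,
            "camera_shape": list(camera.shape),
        },
        median_gain_photon_free=float(g_pf),
        median_gain_traditional=float(g_trad),
        gain_deviation_pct=float(abs(g_pf - g_trad) / g_trad * 100.0),
        true_median_gain=float(np.median(camera.gain)),
    )


def thermal_offset_check(
    camera: CameraGroundTruth,
    t: float,
    n_frames: int = 2000,
    seed: int | None = 0,
) -> float:
    """Mean offset increase (ADU) of a dark stack at exposure ``t`` over the
    thermal-free baseline; equals mean(gain * dark_current) * t up to
    sampling error.  This is the amount by which a fixed-exposure
    characterization overestimates the baseline."""
    if t < 0:
        raise ValueError("exposure time must be >= 0")
    if t == 0:
        return 0.0
    mean, _ = dark_frame_stats(camera, t, n_frames, seed=seed)
    return float(np.mean(mean - camera.baseline))
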