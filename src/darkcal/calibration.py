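"""Photon-free camera characterization from dark-frame series.

Thermally generated electrons obey Poisson statistics exactly like
photoelectrons, so a camera can be characterized completely in the dark by
using exposure time as the "signal level" knob.  Per pixel ``k``:

* mean ADU vs exposure time ``t`` is linear; the y-intersect is the
  baseline ``BL_k`` (ADU) and the slope the dark current (ADU/s);
* variance vs ``t`` is linear; the y-intersect is the read noise squared
  (ADU^2) and the slope the thermal noise squared per time (ADU^2/s);
* variance vs mean is linear with slope equal to the pixel gain
  (ADU/electron), because Poisson signal has variance = mean in electron
  units.

From these, exposure-time-dependent maps follow for any ``t``::

    offset(t)   = BL + dark_current_adu * t
    variance(t) = read_noise_sq + thermal_noise_sq_per_s * t
    photon_response = median_gain * flatfield

All fitted maps are stored in the ADU domain; electron-domain views divide
by the global median gain.  Exposure times are seconds throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .camera import CameraGroundTruth, ExposureSeries

__all__ = [
    "CalibrationError",
    "PixelStats",
    "CalibrationResult",
    "DerivedMaps",
    "RunningStats",
    "pixel_statistics",
    "fit_mean_vs_time",
    "fit_variance_vs_time",
    "fit_variance_vs_mean",
    "aggregate_gain",
    "flatfield_from_bright",
    "derive_maps",
    "true_derived_maps",
    "calibrate",
    "traditional_light_calibration",
]


class CalibrationError(RuntimeError):
    """Raised when a calibration stage cannot proceed."""


class RunningStats:
    """Streaming per-pixel mean/variance accumulator.

    Uses shifted sums (shift = first frame seen) so the sum-of-squares
    cancellation stays at the scale of the actual variance rather than the
    raw pixel values; matches an all-in-memory two-pass computation to
    better than 1e-9 relative for any realistic stack.
    """

    def __init__(self) -> None:
        self._n = 0
        self._shift: np.ndarray | None = None
        self._s1: np.ndarray | None = None
        self._s2: np.ndarray | None = None

    def update(self, frames: np.ndarray) -> None:
        frames = np.asarray(frames)
        if frames.ndim == 2:
            frames = frames[None]
        if frames.ndim != 3:
            raise ValueError("expected a frame or a (n, rows, cols) chunk")
        if self._shift is None:
            self._shift = frames[0].astype(np.float64)
            self._s1 = np.zeros(self._shift.shape)
            self._s2 = np.zeros(self._shift.shape)
        elif frames.shape[1:] != self._shift.shape:
            raise ValueError(
                f"frame shape {frames.shape[1:]} != {self._shift.shape}"
            )
        d = frames.astype(np.float64) - self._shift
        self._s1 += d.sum(axis=0)
        self._s2 += np.square(d).sum(axis=0)
        self._n += frames.shape[0]

    @property
    def n(self) -> int:
        return self._n

    def mean(self) -> np.ndarray:
        if self._n == 0:
            raise CalibrationError("no frames accumulated")
        return self._shift + self._s1 / self._n

    def variance(self) -> np.ndarray:
        """Unbiased (n-1 denominator) per-pixel variance."""
        if self._n < 2:
            raise CalibrationError("variance needs >= 2 frames")
        return np.maximum(self._s2 - self._s1**2 / self._n, 0.0) / (self._n - 1)


@dataclass
class PixelStats:
    """Per-pixel mean/variance summaries of a dark series.

    ``means`` and ``variances`` have shape ``(n_times, rows, cols)`` in ADU
    and ADU^2; ``variances`` uses the unbiased n-1 denominator.
    """

    exposure_times: np.ndarray  # seconds, shape (n_times,)
    means: np.ndarray
    variances: np.ndarray
    n_frames: np.ndarray  # per exposure time

    def __post_init__(self) -> None:
        self.exposure_times = np.asarray(self.exposure_times, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        self.n_frames = np.atleast_1d(np.asarray(self.n_frames))
        if self.means.shape != self.variances.shape:
            raise ValueError("means/variances shape mismatch")
        if self.means.shape[0] != self.exposure_times.size:
            raise ValueError("one mean/variance plane per exposure time")
        if np.any(self.variances < 0):
            raise ValueError("variances must be >= 0")
        if self.n_frames.size == 1:
            self.n_frames = np.full(self.exposure_times.size, int(self.n_frames[0]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.means.shape[1:]


def _stack_stats(stack) -> tuple[np.ndarray, np.ndarray, int]:
    """Mean/variance of one stack (array or iterable of frames/chunks)."""
    rs = RunningStats()
    if isinstance(stack, np.ndarray):
        # chunked even in memory so the code path is identical to streaming
        for i in range(0, stack.shape[0], 256):
            rs.update(stack[i : i + 256])
    else:
        for chunk in stack:
            rs.update(np.asarray(chunk))
    if rs.n < 2:
        raise CalibrationError("need >= 2 frames per stack")
    return rs.mean(), rs.variance(), rs.n


def pixel_statistics(series: ExposureSeries) -> PixelStats:
    """Per-pixel mean and unbiased variance for every exposure time.

    Stacks are consumed chunk-wise, so ``series.frames`` entries may be
    iterables of frames (e.g. lazy TIFF page readers) and the whole series
    never needs to fit in memory at once.
    """
    means, variances, counts = [], [], []
    for stack in series.frames:
        m, v, n = _stack_stats(stack)
        means.append(m)
        variances.append(v)
        counts.append(n)
    if len({m.shape for m in means}) > 1:
        raise CalibrationError("mismatched frame shapes across exposure times")
    return PixelStats(
        exposure_times=np.asarray(series.exposure_times, dtype=float),
        means=np.stack(means),
        variances=np.stack(variances),
        n_frames=np.asarray(counts),
    )


def _ols_lines(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized closed-form OLS of y against x along axis 0.

    ``x`` is either shape ``(n,)`` (shared design) or broadcastable to ``y``
    (per-pixel design).  Returns (intercept, slope, R^2 map).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x.reshape((-1,) + (1,) * (y.ndim - 1))
    xm = x.mean(axis=0)
    ym = y.mean(axis=0)
    xc = x - xm
    yc = y - ym
    sxx = np.square(xc).sum(axis=0)
    sxy = (xc * yc).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
    intercept = ym - slope * xm
    resid = yc - slope * xc
    ss_res = np.square(resid).sum(axis=0)
    ss_tot = np.square(yc).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - ss_res / ss_tot
    # constant response fitted exactly -> define R^2 = 1
    r2 = np.where(ss_tot <= 0, np.where(ss_res <= 1e-30, 1.0, 0.0), r2)
    return intercept, slope, r2


def _check_times(stats: PixelStats, min_times: int) -> np.ndarray:
    t = np.asarray(stats.exposure_times, dtype=float)
    if np.unique(t).size < min_times:
        raise CalibrationError(f"need >= {min_times} distinct exposure times")
    if np.ptp(t) == 0:
        raise CalibrationError("degenerate design: all exposure times identical")
    return t


def fit_mean_vs_time(
    stats: PixelStats, min_times: int = 3
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel OLS of mean ADU against exposure time.

    Returns ``(baseline, dark_current_adu_per_s, r_squared)``: the
    y-intersect is the thermal-free baseline, the slope the dark current in
    ADU/s.
    """
    t = _check_times(stats, min_times)
    intercept, slope, r2 = _ols_lines(t, stats.means)
    return intercept, slope, r2


def fit_variance_vs_time(
    stats: PixelStats, min_times: int = 3
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel OLS of ADU variance against exposure time.

    Returns ``(read_noise_sq_adu, thermal_noise_sq_adu_per_s, r_squared)``.
    Negative intercepts (possible by sampling noise on near-noiseless
    pixels) are retained here and only floored when materializing
    :class:`DerivedMaps`.
    """
    t = _check_times(stats, min_times)
    intercept, slope, r2 = _ols_lines(t, stats.variances)
    return intercept, slope, r2


def fit_variance_vs_mean(
    stats: PixelStats, min_times: int = 3, min_range_sems: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel OLS slope of variance against mean: the pixel gain.

    The intercept is left free (read noise contributes a time-independent
    variance term; only the slope carries the gain).  Pixels whose mean
    spans less than ``min_range_sems`` standard errors of the mean across
    exposure times (e.g. zero-dark-current pixels) have an ill-conditioned
    design; their gain is returned as NaN and excluded from aggregation.
    """
    _check_times(stats, min_times)
    x = stats.means
    y = stats.variances
    _, slope, r2 = _ols_lines(x, y)
    n = stats.n_frames.reshape((-1, 1, 1)).astype(float)
    sem = np.sqrt(stats.variances / n)
    mean_range = x.max(axis=0) - x.min(axis=0)
    degenerate = mean_range < min_range_sems * np.median(sem, axis=0)
    gain = np.where(degenerate, np.nan, slope)
    r2 = np.where(degenerate, np.nan, r2)
    return gain, r2


def aggregate_gain(gain_map: np.ndarray) -> float:
    """Global gain: the median over all valid (non-NaN) pixel gains.

    Single-pixel gains are noisy in the few-electron regime, so the median
    is the robust global summary.
    """
    valid = np.asarray(gain_map, dtype=float)
    valid = valid[np.isfinite(valid)]
    if valid.size == 0:
        raise CalibrationError("no valid pixel gains to aggregate")
    return float(np.median(valid))


def flatfield_from_bright(
    bright: np.ndarray,
    offset: np.ndarray,
    smoothing_sigma: float | None = None,
    saturation: float | None = None,
) -> np.ndarray:
    """Relative sensitivity map from one (averaged) bright frame.

    The offset-subtracted bright signal is divided by a heavily smoothed
    version of itself, which absorbs the illumination profile (vignetting,
    gradients) while leaving pixel-scale sensitivity differences; the result
    is normalized to median 1.  Default smoothing: Gaussian with sigma =
    1/8 of the short image dimension.
    """
    bright = np.asarray(bright, dtype=float)
    offset = np.broadcast_to(np.asarray(offset, dtype=float), bright.shape)
    if saturation is not None:
        frac_sat = np.mean(bright >= saturation)
        if frac_sat > 0.01:
            raise CalibrationError(
                f"bright frame saturated at {frac_sat:.1%} of pixels"
            )
    signal = bright - offset
    if np.median(signal) <= 100:
        raise CalibrationError(
            "bright frame too dim: median offset-subtracted signal <= 100 ADU"
        )
    if smoothing_sigma is None:
        smoothing_sigma = min(bright.shape) / 8.0
    illumination = gaussian_filter(signal, sigma=smoothing_sigma, mode="nearest")
    flat = signal / illumination
    return flat / np.median(flat)


@dataclass
class CalibrationResult:
    """Per-pixel calibration maps (ADU domain) plus diagnostics."""

    baseline: np.ndarray            # ADU
    dark_current_adu: np.ndarray    # ADU / s
    read_noise_sq_adu: np.ndarray   # ADU^2
    thermal_noise_sq_adu: np.ndarray  # ADU^2 / s
    gain: np.ndarray                # ADU / electron (NaN where degenerate)
    median_gain: float
    flatfield: np.ndarray           # dimensionless, median 1
    diagnostics: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.baseline.shape

    # electron-domain views, via the global median gain
    @property
    def dark_current_e(self) -> np.ndarray:
        """Dark current in electrons/s."""
        return self.dark_current_adu / self.median_gain

    @property
    def read_noise_e(self) -> np.ndarray:
        """Read noise (std dev) in electrons; negative fitted intercepts
        floored at zero for the square root."""
        return np.sqrt(np.maximum(self.read_noise_sq_adu, 0.0)) / self.median_gain


@dataclass
class DerivedMaps:
    """Offset, variance and photon-response maps at one exposure time.

    This trio is what map-consuming correction algorithms take as input.
    """

    exposure_time: float      # seconds
    offset: np.ndarray        # ADU
    variance: np.ndarray      # ADU^2 (floored at 0)
    photon_response: np.ndarray  # ADU / photoelectron

    @property
    def shape(self) -> tuple[int, int]:
        return self.offset.shape


def derive_maps(cal: CalibrationResult, t: float) -> DerivedMaps:
    """Evaluate the exposure-time-dependent maps at ``t`` seconds."""
    if t < 0:
        raise ValueError("exposure time must be >= 0")
    offset = cal.baseline + cal.dark_current_adu * t
    variance = np.maximum(cal.read_noise_sq_adu + cal.thermal_noise_sq_adu * t, 0.0)
    photon_response = cal.median_gain * cal.flatfield
    return DerivedMaps(
        exposure_time=float(t),
        offset=offset,
        variance=variance,
        photon_response=photon_response,
    )


def true_derived_maps(gt: CameraGroundTruth, t: float) -> DerivedMaps:
    """Exact maps from a simulator ground truth (oracle counterpart of
    :func:`derive_maps`; photon response is the exact per-pixel
    ``gain * flatfield``)."""
    return DerivedMaps(
        exposure_time=float(t),
        offset=gt.expected_dark_mean(t),
        variance=gt.expected_dark_variance(t),
        photon_response=gt.gain * gt.flatfield,
    )


def calibrate(
    series: ExposureSeries | PixelStats,
    bright_frame: np.ndarray | None = None,
    min_times: int = 3,
    flatfield_smoothing_sigma: float | None = None,
    bit_depth: int | None = None,
) -> CalibrationResult:
    """Run the full photon-free characterization pipeline.

    Accepts a raw :class:`ExposureSeries` or precomputed
    :class:`PixelStats`.  If ``bright_frame`` is given (a single frame or an
    average of many, acquired at the *longest* calibration exposure time),
    a flatfield map is computed; otherwise flatfield is identity and the
    photon response map is uniform at the median gain.
    """
    if isinstance(series, PixelStats):
        stats = series
    else:
        if bit_depth is None:
            bit_depth = series.bit_depth
        stats = pixel_statistics(series)

    try:
        baseline, dc_adu, r2_mean = fit_mean_vs_time(stats, min_times)
        rn_sq, tn_sq, r2_var = fit_variance_vs_time(stats, min_times)
        gain, r2_gain = fit_variance_vs_mean(stats, min_times)
        median_gain = aggregate_gain(gain)
    except CalibrationError as err:
        raise CalibrationError(f"calibration fits failed: {err}") from err

    if bright_frame is not None:
        # offset at the bright frame's exposure time: use the longest
        # calibration time, where the thermal contribution is largest
        t_bright = float(np.max(stats.exposure_times))
        offset_b = baseline + dc_adu * t_bright
        sat = (2**bit_depth - 1) if bit_depth else None
        try:
            flatfield = flatfield_from_bright(
                bright_frame, offset_b, flatfield_smoothing_sigma, saturation=sat
            )
        except CalibrationError as err:
            raise CalibrationError(f"flatfield stage failed: {err}") from err
    else:
        flatfield = np.ones_like(baseline)

    saturated = 0
    if bit_depth:
        saturated = int(np.sum(stats.means.max(axis=0) >= 2**bit_depth - 2))
    diagnostics = {
        "median_r2_mean_fit": float(np.nanmedian(r2_mean)),
        "median_r2_variance_fit": float(np.nanmedian(r2_var)),
        "median_r2_gain_fit": float(np.nanmedian(r2_gain)),
        "n_negative_baseline": int(np.sum(baseline < 0)),
        "n_negative_read_noise_sq": int(np.sum(rn_sq < 0)),
        "n_missing_gain": int(np.sum(~np.isfinite(gain))),
        "n_saturated": saturated,
        "n_frames_per_time": [int(n) for n in np.atleast_1d(stats.n_frames)],
        "exposure_times_s": [float(t) for t in stats.exposure_times],
        "median_dark_current_e_per_s": float(
            np.median(dc_adu) / median_gain
        ),
        "median_read_noise_e": float(
            np.sqrt(max(np.median(rn_sq), 0.0)) / median_gain
        ),
        "r2_mean_fit": r2_mean,
        "r2_variance_fit": r2_var,
        "r2_gain_fit": r2_gain,
    }
    return CalibrationResult(
        baseline=baseline,
        dark_current_adu=dc_adu,
        read_noise_sq_adu=rn_sq,
        thermal_noise_sq_adu=tn_sq,
        gain=gain,
        median_gain=median_gain,
        flatfield=flatfield,
        diagnostics=diagnostics,
    )


def traditional_light_calibration(
    light_stacks: Mapping[float, object],
    exposure_time: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Traditional varying-light-level characterization at one exposure time.

    ``light_stacks`` maps nominal light level (expected photoelectrons per
    pixel; the value 0 marks the darkness stack) to a frame stack or
    iterable of frames.  The offset and variance maps come from the darkness
    stack at this exposure time — which is why they include the thermal
    contribution ``dark_current * t`` that the photon-free method separates
    out — and the per-pixel gain is the OLS slope of variance against mean
    across light levels.
    """
    levels = sorted(light_stacks)
    if len(levels) < 3:
        raise CalibrationError("need >= 3 light levels")
    if 0 not in levels and 0.0 not in levels:
        raise CalibrationError("light levels must include darkness (level 0)")
    if len(set(levels)) != len(levels):
        raise CalibrationError("degenerate (repeated) light levels")

    means, variances = [], []
    for level in levels:
        m, v, _ = _stack_stats(light_stacks[level])
        means.append(m)
        variances.append(v)
    means = np.stack(means)
    variances = np.stack(variances)

    offset = means[levels.index(0)]
    variance = variances[levels.index(0)]
    _, gain, _ = _ols_lines(means, variances)
    return offset, variance, gain
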