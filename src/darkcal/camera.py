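"""Parametric per-pixel CMOS/sCMOS camera model and synthetic frame generation.

The camera is described pixel-wise by five maps:

``baseline``
    Offset in ADU free of thermal contributions, i.e. the expected dark
    signal extrapolated to zero exposure time.
``dark_current``
    Thermally generated electrons per second.  Thermal electron counts are
    Poisson distributed, so the thermal-noise variance per second (in
    electron units) *is* the dark-current rate — the model never carries an
    independent thermal-noise parameter.
``read_noise``
    Exposure-time-independent Gaussian readout noise (standard deviation,
    electrons).
``gain``
    Conversion factor from electrons to ADU counts (ADU/electron).
``flatfield``
    Relative photon sensitivity (dimensionless, mean ~ 1).  It scales the
    photon rate before Poisson detection and does not affect dark frames.

A dark frame is simulated per pixel ``k`` as::

    ADU_k = clip(round(BL_k + gain_k * (Poisson(DC_k * t) + Normal(0, RN_k))),
                 0, 2**bit_depth - 1)

so the expected ADU mean is ``BL + gain*DC*t`` and the expected ADU variance
is ``gain^2 * (RN^2 + DC*t)`` up to quantization and clipping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterator, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "CameraGroundTruth",
    "ExposureSeries",
    "make_synthetic_camera",
    "simulate_dark_frames",
    "iter_dark_frames",
    "dark_frame_stats",
    "simulate_dark_series",
    "simulate_bright_frame",
    "simulate_bright_frames",
    "bright_frame_stats",
]

#: default parameter ranges for synthetic cameras; magnitudes follow typical
#: uncooled CMOS sensors (baseline ~100 ADU, read noise 1-2 e-, dark current
#: a few tens of e-/s with a heavy tail, gain ~2 ADU/e-, flatfield within 2%).
DEFAULT_PARAMETER_RANGES: dict[str, tuple[float, float]] = {
    "baseline": (100.0, 4.0),      # mean ADU, smooth spatial std
    "dark_current": (28.0, 0.45),  # median e-/s, log-normal sigma
    "read_noise": (1.5, 0.25),     # mean e-, pixel-to-pixel std
    "gain": (2.0, 0.05),           # mean ADU/e-, pixel-to-pixel std
    "flatfield": (1.0, 0.02),      # mean, smooth spatial std
    "hot_multiplier": (10.0, 30.0),  # uniform range, x median dark current
}


@dataclass(frozen=True)
class CameraGroundTruth:
    """True per-pixel physical parameters of a simulated camera."""

    baseline: np.ndarray
    dark_current: np.ndarray
    read_noise: np.ndarray
    gain: np.ndarray
    flatfield: np.ndarray
    bit_depth: int = 16
    hot_pixels: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        maps = {
            "baseline": self.baseline,
            "dark_current": self.dark_current,
            "read_noise": self.read_noise,
            "gain": self.gain,
            "flatfield": self.flatfield,
        }
        shape = self.baseline.shape
        for name, m in maps.items():
            if m.shape != shape:
                raise ValueError(f"map {name!r} has shape {m.shape}, expected {shape}")
        if np.any(self.dark_current < 0):
            raise ValueError("dark_current must be >= 0")
        if np.any(self.read_noise < 0):
            raise ValueError("read_noise must be >= 0")
        if np.any(self.gain <= 0):
            raise ValueError("gain must be > 0")
        if np.any(self.flatfield <= 0):
            raise ValueError("flatfield must be > 0")
        if self.bit_depth < 1:
            raise ValueError("bit_depth must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.baseline.shape

    @property
    def saturation(self) -> int:
        return 2**self.bit_depth - 1

    def expected_dark_mean(self, t: float) -> np.ndarray:
        """Expected dark ADU mean at exposure time ``t`` (seconds)."""
        return self.baseline + self.gain * self.dark_current * t

    def expected_dark_variance(self, t: float) -> np.ndarray:
        """Expected dark ADU variance at exposure time ``t`` (seconds),
        ignoring quantization (which adds ~1/12 ADU^2) and clipping."""
        return self.gain**2 * (self.read_noise**2 + self.dark_current * t)

    def crop(self, origin: tuple[int, int], shape: tuple[int, int]) -> "CameraGroundTruth":
        r0, c0 = origin
        h, w = shape
        if r0 < 0 or c0 < 0 or r0 + h > self.shape[0] or c0 + w > self.shape[1]:
            raise ValueError("crop region outside camera")
        sl = (slice(r0, r0 + h), slice(c0, c0 + w))
        hot = tuple(
            (r - r0, c - c0)
            for (r, c) in self.hot_pixels
            if r0 <= r < r0 + h and c0 <= c < c0 + w
        )
        return replace(
            self,
            baseline=self.baseline[sl],
            dark_current=self.dark_current[sl],
            read_noise=self.read_noise[sl],
            gain=self.gain[sl],
            flatfield=self.flatfield[sl],
            hot_pixels=hot,
        )


@dataclass
class ExposureSeries:
    """Dark-frame stacks keyed by exposure time.

    ``frames[i]`` is the stack (``n x H x W`` integer ADU array, or an
    iterable of frames/chunks for streaming consumption) acquired at
    ``exposure_times[i]`` (seconds).  ``schedule`` records whether the frames
    were acquired interleaved round-robin over exposure times ("nested",
    which keeps the average detector heat load constant) or one exposure
    time after another ("blocked").
    """

    exposure_times: tuple[float, ...]
    frames: list
    schedule: str = "nested"
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.schedule not in ("nested", "blocked"):
            raise ValueError(f"unknown schedule {self.schedule!r}")
        if len(self.exposure_times) != len(self.frames):
            raise ValueError("one frame stack required per exposure time")
        counts = set()
        shape = None
        for stack in self.frames:
            if isinstance(stack, np.ndarray):
                if stack.ndim != 3:
                    raise ValueError("frame stacks must be (n, rows, cols)")
                counts.add(stack.shape[0])
                if shape is None:
                    shape = stack.shape[1:]
                elif stack.shape[1:] != shape:
                    raise ValueError("all frames must share one shape")
                if stack.min() < 0 or stack.max() > 2**self.bit_depth - 1:
                    raise ValueError("frame values outside ADU range")
        if len(counts) > 1:
            raise ValueError("each exposure time needs the same frame count")


def as_seed_sequence(seed) -> np.random.SeedSequence:
    """Normalize an int/None/SeedSequence seed to a SeedSequence."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma_px: float) -> np.ndarray:
    """Unit-variance smooth random field (Gaussian-filtered white noise)."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma_px, mode="wrap")
    s = f.std()
    if s == 0:
        return np.zeros(shape)
    return (f - f.mean()) / s


def make_synthetic_camera(
    shape: tuple[int, int],
    hot_pixel_fraction: float = 0.01,
    parameter_ranges: dict[str, tuple[float, float]] | None = None,
    seed: int | None = None,
    bit_depth: int = 16,
    high_read_noise_pixels: bool = False,
) -> CameraGroundTruth:
    """Generate a synthetic camera ground truth.

    Baseline and flatfield vary smoothly over the chip; dark current is
    log-normal with a designated ``hot_pixel_fraction`` of pixels boosted to
    at least 10x the median; read noise and gain scatter pixel-to-pixel
    around their global values.  Deterministic for a fixed ``seed``.

    Parameters
    ----------
    shape
        Pixel grid ``(rows, cols)``.
    hot_pixel_fraction
        Fraction of pixels turned into high-dark-current defects
        (``round(fraction * n_pixels)`` pixels, coordinates recorded in
        :attr:`CameraGroundTruth.hot_pixels`).
    parameter_ranges
        Overrides merged over :data:`DEFAULT_PARAMETER_RANGES`; each entry is
        a ``(center, spread)`` pair (median and log-sigma for dark current,
        mean and std otherwise; ``hot_multiplier`` is a uniform range).
    high_read_noise_pixels
        Also give hot pixels 3x read noise (off by default: camera defects
        are modelled as dark-current-dominated).
    """
    rows, cols = shape
    if rows < 1 or cols < 1:
        raise ValueError(f"invalid shape {shape}")
    if not 0 <= hot_pixel_fraction < 1:
        raise ValueError("hot_pixel_fraction must be in [0, 1)")
    ranges = dict(DEFAULT_PARAMETER_RANGES)
    if parameter_ranges:
        unknown = set(parameter_ranges) - set(ranges)
        if unknown:
            raise ValueError(f"unknown parameter ranges: {sorted(unknown)}")
        ranges.update(parameter_ranges)
    for name, (a, b) in ranges.items():
        if a <= 0 or b < 0:
            raise ValueError(f"parameter range {name!r} must be positive")

    rng = np.random.default_rng(seed)
    smooth_sigma = max(min(rows, cols) / 8.0, 1.0)

    bl_mean, bl_spread = ranges["baseline"]
    baseline = bl_mean + bl_spread * _smooth_field(rng, shape, smooth_sigma)

    dc_median, dc_sigma = ranges["dark_current"]
    dark_current = dc_median * np.exp(rng.normal(0.0, dc_sigma, shape))

    n_hot = int(round(hot_pixel_fraction * rows * cols))
    hot_pixels: tuple[tuple[int, int], ...] = ()
    if n_hot:
        flat_idx = rng.choice(rows * cols, size=n_hot, replace=False)
        hr, hc = np.unravel_index(flat_idx, shape)
        lo, hi = ranges["hot_multiplier"]
        mult = rng.uniform(lo, hi, n_hot)
        dark_current[hr, hc] = np.median(dark_current) * mult
        hot_pixels = tuple(sorted(zip(hr.tolist(), hc.tolist())))

    rn_mean, rn_spread = ranges["read_noise"]
    read_noise = np.clip(rn_mean + rn_spread * rng.standard_normal(shape), 0.1 * rn_mean, None)
    if high_read_noise_pixels and n_hot:
        hr = np.array([p[0] for p in hot_pixels])
        hc = np.array([p[1] for p in hot_pixels])
        read_noise[hr, hc] *= 3.0

    g_mean, g_spread = ranges["gain"]
    gain = np.clip(g_mean + g_spread * rng.standard_normal(shape), 0.2 * g_mean, None)

    ff_mean, ff_spread = ranges["flatfield"]
    flatfield = ff_mean + ff_spread * _smooth_field(rng, shape, smooth_sigma)
    flatfield = np.clip(flatfield, 0.5 * ff_mean, None)

    return CameraGroundTruth(
        baseline=baseline,
        dark_current=dark_current,
        read_noise=read_noise,
        gain=gain,
        flatfield=flatfield,
        bit_depth=bit_depth,
        hot_pixels=hot_pixels,
    )


def _draw_frames(
    gt: CameraGroundTruth,
    electron_rate: np.ndarray,
    n_frames: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n_frames`` quantized ADU frames for a Poisson electron rate map."""
    size = (n_frames,) + gt.shape
    electrons = rng.poisson(electron_rate, size=size).astype(np.float64)
    rn = gt.read_noise
    if np.any(rn > 0):
        electrons += rng.standard_normal(size) * rn
    adu = np.rint(gt.baseline + gt.gain * electrons)
    np.clip(adu, 0, gt.saturation, out=adu)
    return adu.astype(np.uint16 if gt.bit_depth <= 16 else np.uint32)


def simulate_dark_frames(
    gt: CameraGroundTruth, t: float, n_frames: int, seed: int | None = None
) -> np.ndarray:
    """Simulate a stack of dark frames at exposure time ``t`` (seconds)."""
    if t < 0:
        raise ValueError("exposure time must be >= 0")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    return _draw_frames(gt, gt.dark_current * t, n_frames, rng)


def iter_dark_frames(
    gt: CameraGroundTruth,
    t: float,
    n_frames: int,
    seed: int | None = None,
    chunk_frames: int = 256,
) -> Iterator[np.ndarray]:
    """Yield dark frames in chunks of at most ``chunk_frames`` frames.

    Concatenating all chunks reproduces :func:`simulate_dark_frames` draws
    with the same seed only when ``chunk_frames >= n_frames``; chunked draws
    are deterministic for a fixed (seed, chunk_frames) pair.
    """
    if t < 0:
        raise ValueError("exposure time must be >= 0")
    rng = np.random.default_rng(seed)
    rate = gt.dark_current * t
    done = 0
    while done < n_frames:
        k = min(chunk_frames, n_frames - done)
        yield _draw_frames(gt, rate, k, rng)
        done += k


def dark_frame_stats(
    gt: CameraGroundTruth,
    t: float,
    n_frames: int,
    seed: int | None = None,
    chunk_frames: int = 256,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel (mean, unbiased variance) of freshly simulated dark frames,
    computed streaming so only one chunk is resident at a time."""
    from .calibration import RunningStats

    rs = RunningStats()
    for chunk in iter_dark_frames(gt, t, n_frames, seed, chunk_frames):
        rs.update(chunk)
    return rs.mean(), rs.variance()


def simulate_dark_series(
    gt: CameraGroundTruth,
    exposure_times: Sequence[float],
    n_per_time: int,
    seed: int | None = None,
    schedule: str = "nested",
) -> ExposureSeries:
    """Simulate dark stacks at several exposure times.

    Each exposure time draws from its own child RNG stream, so the per-time
    stacks are identical between the "nested" (interleaved) and "blocked"
    acquisition orders — the simulated detector has no temperature drift, so
    the schedule can only matter through bookkeeping.
    """
    times = tuple(float(t) for t in exposure_times)
    if len(set(times)) < 3:
        raise ValueError("need >= 3 distinct exposure times")
    seq = as_seed_sequence(seed)
    children = seq.spawn(len(times))
    stacks = []
    for t, child in zip(times, children):
        rng = np.random.default_rng(child)
        stacks.append(_draw_frames(gt, gt.dark_current * t, n_per_time, rng))
    return ExposureSeries(
        exposure_times=times, frames=stacks, schedule=schedule, bit_depth=gt.bit_depth
    )


def simulate_bright_frames(
    gt: CameraGroundTruth,
    photons_per_pixel: float,
    t: float,
    n_frames: int = 1,
    seed: int | None = None,
    illumination_profile: np.ndarray | Callable[[tuple[int, int]], np.ndarray] | None = None,
) -> np.ndarray:
    """Simulate uniformly (or profiled) illuminated frames.

    ``photons_per_pixel`` is the expected number of incident photoelectrons
    for a unit-sensitivity pixel; the per-pixel Poisson rate is
    ``flatfield * profile * photons + dark_current * t``.
    """
    if photons_per_pixel < 0:
        raise ValueError("photons_per_pixel must be >= 0")
    if t < 0:
        raise ValueError("exposure time must be >= 0")
    if callable(illumination_profile):
        profile = np.asarray(illumination_profile(gt.shape), dtype=float)
    elif illumination_profile is None:
        profile = 1.0
    else:
        profile = np.asarray(illumination_profile, dtype=float)
    rate = gt.flatfield * profile * photons_per_pixel + gt.dark_current * t
    rng = np.random.default_rng(seed)
    return _draw_frames(gt, rate, n_frames, rng)


def simulate_bright_frame(
    gt: CameraGroundTruth,
    photons_per_pixel: float,
    illumination_profile: np.ndarray | None = None,
    t: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Single bright frame; see :func:`simulate_bright_frames`."""
    return simulate_bright_frames(
        gt, photons_per_pixel, t, 1, seed, illumination_profile
    )[0]


def bright_frame_stats(
    gt: CameraGroundTruth,
    photons_per_pixel: float,
    t: float,
    n_frames: int,
    seed: int | None = None,
    chunk_frames: int = 256,
) -> tuple[np.ndarray, np.ndarray]:
    """Streaming per-pixel (mean, variance) of simulated bright frames."""
    from .calibration import RunningStats

    if photons_per_pixel < 0:
        raise ValueError("photons_per_pixel must be >= 0")
    rng = np.random.default_rng(seed)
    rate = gt.flatfield * photons_per_pixel + gt.dark_current * t
    rs = RunningStats()
    done = 0
    while done < n_frames:
        k = min(chunk_frames, n_frames - done)
        rs.update(_draw_frames(gt, rate, k, rng))
        done += k
    return rs.mean(), rs.variance()
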