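"""SMLM frame simulation through the camera model and bias/RMSE studies.

A single-emitter ROI is simulated exactly as the camera sees it: the
expected photoelectron map (PSF integral times photon count plus uniform
background) is scaled by the pixel flatfield, dark-current electrons for
the frame exposure time are added to the Poisson rate, Gaussian read noise
is added in electron units, and the result is gain-converted, offset,
rounded and clipped to the ADU range.

``bias_rmse_experiment`` places emitters on camera-pixel centers over a
grid, simulates many repeats per position, and fits each stack twice: with
the per-pixel exposure-time-dependent maps ("corrected") and with
field-average scalar camera constants ("uncorrected").  Bias is the
deviation of the mean fitted coordinate from the ground truth; RMSE and the
theoretical sqrt-CRLB are reported per axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .calibration import DerivedMaps, true_derived_maps
from .camera import CameraGroundTruth, as_seed_sequence
from .fitting import crlb, fit_roi_batch
from .psf import PSFModel, psf_pixel_integrals

__all__ = [
    "EmitterTruth",
    "Modality",
    "modality_preset",
    "MODALITY_EXPOSURES_S",
    "PHOTON_PRESETS",
    "simulate_smlm_frames",
    "BiasExperimentConfig",
    "BiasReport",
    "bias_rmse_experiment",
]

#: mean signal photons per emitter and frame, by modality and camera grade
PHOTON_PRESETS: dict[str, dict[str, float]] = {
    "scmos": {"palm": 3420.0, "storm": 9000.0, "paint": 35100.0},
    "industry": {"palm": 1900.0, "storm": 5000.0, "paint": 19500.0},
}

#: single-frame exposure times (seconds) by modality
MODALITY_EXPOSURES_S: dict[str, float] = {"palm": 0.05, "storm": 0.05, "paint": 0.5}

#: default uniform background, photoelectrons / pixel / frame
DEFAULT_BACKGROUND: dict[str, float] = {"palm": 10.0, "storm": 30.0, "paint": 50.0}


@dataclass(frozen=True)
class Modality:
    """An SMLM imaging modality preset."""

    name: str
    photons: float
    exposure_s: float
    background: float


def modality_preset(name: str, camera_grade: str = "scmos", background: float | None = None) -> Modality:
    """PALM / STORM / DNA-PAINT presets (photon counts by camera grade)."""
    name = name.lower()
    if name not in MODALITY_EXPOSURES_S:
        raise ValueError(f"unknown modality {name!r}; choose palm, storm or paint")
    if camera_grade not in PHOTON_PRESETS:
        raise ValueError(f"unknown camera grade {camera_grade!r}")
    return Modality(
        name=name,
        photons=PHOTON_PRESETS[camera_grade][name],
        exposure_s=MODALITY_EXPOSURES_S[name],
        background=DEFAULT_BACKGROUND[name] if background is None else background,
    )


@dataclass(frozen=True)
class EmitterTruth:
    """Ground-truth emitter: position in nm within the ROI, expected signal
    photoelectrons per frame, uniform background photoelectrons/pixel/frame."""

    x: float
    y: float
    z: float = 0.0
    photons: float = 5000.0
    background: float = 10.0

    def __post_init__(self) -> None:
        if self.photons <= 0:
            raise ValueError("photons must be > 0")
        if self.background < 0:
            raise ValueError("background must be >= 0")


def simulate_smlm_frames(
    gt_camera: CameraGroundTruth,
    psf: PSFModel,
    emitter: EmitterTruth,
    t: float,
    n_repeats: int,
    photon_mode: str = "fixed",
    photon_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    seed: int | None = None,
    origin: tuple[int, int] = (0, 0),
    roi_shape: tuple[int, int] = (13, 13),
) -> tuple[np.ndarray, dict]:
    """Simulate a stack of noisy single-emitter ROIs.

    ``origin`` is the (row, col) of the ROI's top-left pixel on the camera;
    the emitter position is relative to the ROI.  ``photon_mode`` is
    ``"fixed"`` (every repeat uses ``emitter.photons``, the protocol for
    RMSE studies) or ``"distribution"`` (draw per-repeat photon counts from
    ``photon_sampler(rng, n)``).  Returns (stack, truth record).
    """
    if t <= 0:
        raise ValueError("exposure time must be > 0")
    cam = gt_camera.crop(origin, roi_shape)
    E = psf_pixel_integrals(psf, emitter.x, emitter.y, emitter.z, roi_shape)
    rng = np.random.default_rng(seed)
    if photon_mode == "fixed":
        N = np.full(n_repeats, float(emitter.photons))
    elif photon_mode == "distribution":
        if photon_sampler is None:
            raise ValueError("photon_mode='distribution' needs a photon_sampler")
        N = np.asarray(photon_sampler(rng, n_repeats), dtype=float)
    else:
        raise ValueError(f"unknown photon_mode {photon_mode!r}")

    rate = cam.flatfield * (N[:, None, None] * E + emitter.background) + cam.dark_current * t
    electrons = rng.poisson(rate).astype(np.float64)
    electrons += rng.standard_normal(rate.shape) * cam.read_noise
    adu = np.rint(cam.baseline + cam.gain * electrons)
    np.clip(adu, 0, cam.saturation, out=adu)
    truth = {
        "x": emitter.x,
        "y": emitter.y,
        "z": emitter.z,
        "photons": N,
        "background": emitter.background,
        "origin": origin,
        "roi_shape": roi_shape,
        "exposure_s": t,
    }
    return adu.astype(np.uint16 if gt_camera.bit_depth <= 16 else np.uint32), truth


def _crop_maps(maps: DerivedMaps, origin: tuple[int, int], roi_shape: tuple[int, int]) -> DerivedMaps:
    r0, c0 = origin
    h, w = roi_shape
    sl = (slice(r0, r0 + h), slice(c0, c0 + w))
    return DerivedMaps(
        exposure_time=maps.exposure_time,
        offset=maps.offset[sl],
        variance=maps.variance[sl],
        photon_response=maps.photon_response[sl],
    )


def _scalar_maps(maps: DerivedMaps) -> DerivedMaps:
    """Field-average camera constants (the uncorrected fitter's view)."""
    return DerivedMaps(
        exposure_time=maps.exposure_time,
        offset=np.asarray([[float(np.mean(maps.offset))]]),
        variance=np.asarray([[float(np.mean(maps.variance))]]),
        photon_response=np.asarray([[float(np.mean(maps.photon_response))]]),
    )


@dataclass
class BiasExperimentConfig:
    """Configuration for a bias/RMSE grid experiment.

    ``grid`` lists camera pixel (row, col) indices; each emitter sits on
    that pixel's center.  ``maps`` defaults to the exact maps of the
    ground-truth camera at the modality's exposure time (use
    :func:`~darkcal.calibration.derive_maps` output to study a calibrated
    camera instead).
    """

    camera: CameraGroundTruth
    psf: PSFModel
    modality: Modality
    grid: Sequence[tuple[int, int]]
    n_repeats: int = 1000
    roi_halfsize: int = 6
    seed: int | None = None
    photon_mode: str = "fixed"
    photon_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None
    maps: DerivedMaps | None = None


@dataclass
class BiasReport:
    """Per-position bias/RMSE/sqrt-CRLB table (nm) for corrected and
    uncorrected fitting; one row per grid position."""

    table: pd.DataFrame
    modality: Modality
    n_repeats: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def bias_map(self, column: str) -> np.ndarray:
        """Pivot one column into a (row, col) image over the grid."""
        return self.table.pivot(index="row", columns="col", values=column).to_numpy()


def _axis_cols(psf: PSFModel) -> list[str]:
    return ["x", "y", "z"] if psf.n_params == 5 else ["x", "y"]


def bias_rmse_experiment(config: BiasExperimentConfig) -> BiasReport:
    """Run the grid bias/RMSE study; see module docstring."""
    cam = config.camera
    psf = config.psf
    mod = config.modality
    t = mod.exposure_s
    maps = config.maps if config.maps is not None else true_derived_maps(cam, t)
    scalar = _scalar_maps(maps)
    h = config.roi_halfsize
    roi_shape = (2 * h + 1, 2 * h + 1)
    axes = _axis_cols(psf)
    px = psf.pixel_size

    hot = np.array(cam.hot_pixels, dtype=float).reshape(-1, 2)
    seq = as_seed_sequence(config.seed)
    children = seq.spawn(len(config.grid))

    rows = []
    for (r, c), child in zip(config.grid, children):
        origin = (r - h, c - h)
        if origin[0] < 0 or origin[1] < 0 or origin[0] + roi_shape[0] > cam.shape[0] or origin[1] + roi_shape[1] > cam.shape[1]:
            raise ValueError(f"grid position {(r, c)} puts ROI outside camera")
        emitter = EmitterTruth(
            x=(h + 0.5) * px,
            y=(h + 0.5) * px,
            z=0.0,
            photons=mod.photons,
            background=mod.background,
        )
        stack, truth = simulate_smlm_frames(
            cam, psf, emitter, t, config.n_repeats,
            photon_mode=config.photon_mode, photon_sampler=config.photon_sampler,
            seed=child, origin=origin, roi_shape=roi_shape,
        )
        roi_maps = _crop_maps(maps, origin, roi_shape)
        truth_vals = {"x": emitter.x, "y": emitter.y, "z": emitter.z}
        theta_true = {
            "x": emitter.x, "y": emitter.y, "z": emitter.z,
            "photons": float(np.mean(truth["photons"])), "background": mod.background,
        }
        bounds = crlb(psf, theta_true, roi_maps, roi_shape)

        row: dict = {"row": r, "col": c}
        if hot.size:
            row["hot_distance_px"] = float(
                np.min(np.hypot(hot[:, 0] - r, hot[:, 1] - c))
            )
        else:
            row["hot_distance_px"] = np.inf
        for label, use_maps, corrected in (
            ("corrected", roi_maps, True),
            ("uncorrected", scalar, False),
        ):
            est, conv, _, _ = fit_roi_batch(stack, use_maps, psf, corrected=corrected)
            row[f"{label}_converged_frac"] = float(np.mean(conv))
            for ax in axes:
                err = est[ax] - truth_vals[ax]
                row[f"{label}_bias_{ax}"] = float(np.mean(err))
                row[f"{label}_rmse_{ax}"] = float(np.sqrt(np.mean(err**2)))
                row[f"{label}_std_{ax}"] = float(np.std(err))
        for ax in axes:
            row[f"sqrt_crlb_{ax}"] = float(np.sqrt(bounds[ax]))
        rows.append(row)

    return BiasReport(table=pd.DataFrame(rows), modality=mod, n_repeats=config.n_repeats)
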