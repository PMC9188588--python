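"""TIFF/YAML/JSON readers and writers for stacks, maps and manifests.

Frame stacks are multi-page TIFF (16-bit for raw frames); calibration and
derived maps are 32-bit float single-page TIFFs with canonical names::

    baseline.tif, dark_current_per_s.tif, read_noise_sq.tif,
    thermal_noise_sq_per_s.tif, gain.tif, flatfield.tif
    offset_<t>ms.tif, variance_<t>ms.tif, photon_response.tif

A JSON sidecar records units and provenance; YAML manifests describe
acquisition schedules with explicit time units ("ms" or "s").
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterator

import numpy as np
import tifffile
import yaml

from .calibration import CalibrationResult, DerivedMaps

__all__ = [
    "read_stack",
    "iter_pages",
    "write_stack",
    "write_maps",
    "read_derived_maps",
    "read_calibration",
    "write_manifest",
    "read_manifest",
]

_CAL_FILES = {
    "baseline": "baseline.tif",
    "dark_current_adu": "dark_current_per_s.tif",
    "read_noise_sq_adu": "read_noise_sq.tif",
    "thermal_noise_sq_adu": "thermal_noise_sq_per_s.tif",
    "gain": "gain.tif",
    "flatfield": "flatfield.tif",
}


def _ms_tag(t_seconds: float) -> str:
    ms = t_seconds * 1e3
    return f"{ms:g}ms"


def read_stack(path) -> tuple[np.ndarray, dict]:
    """Read a multi-page TIFF stack as (frames, metadata)."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        shapes = {p.shape for p in tif.pages}
        if len(shapes) > 1:
            raise ValueError(f"{path}: mixed page shapes {shapes}")
        data = tif.asarray()
    if data.ndim == 2:
        data = data[None]
    return data, {"path": str(path), "n_frames": data.shape[0], "dtype": str(data.dtype)}


def iter_pages(path, chunk_frames: int = 64) -> Iterator[np.ndarray]:
    """Lazily yield chunks of pages from a multi-page TIFF, keeping O(chunk)
    frames resident — suitable for streaming pixel statistics."""
    with tifffile.TiffFile(path) as tif:
        buf = []
        for page in tif.pages:
            buf.append(page.asarray())
            if len(buf) >= chunk_frames:
                yield np.stack(buf)
                buf = []
        if buf:
            yield np.stack(buf)


def write_stack(path, frames: np.ndarray, metadata: dict | None = None) -> None:
    """Write a frame stack as a multi-page TIFF (deterministic: no timestamp)."""
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    tifffile.imwrite(Path(path), frames, metadata=metadata or {})


def write_maps(
    maps: CalibrationResult | DerivedMaps,
    out_dir,
    overwrite: bool = False,
    provenance: dict | None = None,
) -> list[Path]:
    """Write calibration or derived maps as float32 TIFFs + JSON sidecar."""
    out = Path(out_dir)
    if out.exists() and not overwrite and any(out.iterdir()):
        raise FileExistsError(f"{out} exists and is not empty; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)

    written: list[Path] = []

    def _write(name: str, arr: np.ndarray) -> None:
        p = out / name
        if not np.all(np.isfinite(arr)) and "gain" not in name:
            raise ValueError(f"map {name} contains non-finite values")
        tifffile.imwrite(p, np.asarray(arr, dtype=np.float32))
        written.append(p)

    sidecar: dict = {"units": {}, "provenance": provenance or {}}
    if isinstance(maps, CalibrationResult):
        for attr, fname in _CAL_FILES.items():
            _write(fname, getattr(maps, attr))
        sidecar["units"] = {
            "baseline.tif": "ADU",
            "dark_current_per_s.tif": "ADU/s",
            "read_noise_sq.tif": "ADU^2",
            "thermal_noise_sq_per_s.tif": "ADU^2/s",
            "gain.tif": "ADU/electron",
            "flatfield.tif": "dimensionless",
        }
        sidecar["median_gain"] = maps.median_gain
        diag = {
            k: v for k, v in maps.diagnostics.items() if not isinstance(v, np.ndarray)
        }
        sidecar["diagnostics"] = diag
    elif isinstance(maps, DerivedMaps):
        tag = _ms_tag(maps.exposure_time)
        _write(f"offset_{tag}.tif", maps.offset)
        _write(f"variance_{tag}.tif", maps.variance)
        _write("photon_response.tif", maps.photon_response)
        sidecar["units"] = {
            f"offset_{tag}.tif": "ADU",
            f"variance_{tag}.tif": "ADU^2",
            "photon_response.tif": "ADU/photoelectron",
        }
        sidecar["exposure_time_s"] = maps.exposure_time
    else:
        raise TypeError(f"cannot write maps of type {type(maps).__name__}")

    with open(out / "maps.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, default=str)
    written.append(out / "maps.json")
    return written


def read_calibration(map_dir) -> CalibrationResult:
    """Read a calibration written by :func:`write_maps`."""
    d = Path(map_dir)
    arrays = {attr: tifffile.imread(d / fname).astype(float) for attr, fname in _CAL_FILES.items()}
    with open(d / "maps.json") as fh:
        sidecar = json.load(fh)
    return CalibrationResult(
        median_gain=float(sidecar["median_gain"]),
        diagnostics=sidecar.get("diagnostics", {}),
        **arrays,
    )


def read_derived_maps(map_dir, exposure_time_s: float | None = None) -> DerivedMaps:
    """Read a derived-map trio written by :func:`write_maps`."""
    d = Path(map_dir)
    with open(d / "maps.json") as fh:
        sidecar = json.load(fh)
    t = exposure_time_s if exposure_time_s is not None else float(sidecar["exposure_time_s"])
    tag = _ms_tag(t)
    return DerivedMaps(
        exposure_time=t,
        offset=tifffile.imread(d / f"offset_{tag}.tif").astype(float),
        variance=tifffile.imread(d / f"variance_{tag}.tif").astype(float),
        photon_response=tifffile.imread(d / "photon_response.tif").astype(float),
    )


def write_manifest(path, manifest: dict) -> None:
    """Write an acquisition manifest (YAML).  ``exposure_times`` must carry
    an explicit ``unit`` key ("ms" or "s")."""
    unit = manifest.get("exposure_time_unit")
    if unit not in ("ms", "s"):
        raise ValueError("manifest needs exposure_time_unit of 'ms' or 's'")
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def read_manifest(path) -> dict:
    """Read a manifest and normalize exposure times to seconds under the
    key ``exposure_times_s``."""
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    unit = manifest.get("exposure_time_unit")
    if unit not in ("ms", "s"):
        raise ValueError("manifest needs exposure_time_unit of 'ms' or 's'")
    scale = 1e-3 if unit == "ms" else 1.0
    manifest["exposure_times_s"] = [float(t) * scale for t in manifest["exposure_times"]]
    return manifest
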