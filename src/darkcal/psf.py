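"""Gaussian PSF models with per-pixel integration.

Two point-spread-function models are provided:

* ``gauss2d`` — an isotropic 2D Gaussian of in-focus width ``sigma0``;
* ``astigmatic3d`` — an elliptical Gaussian whose x/y widths encode the
  axial position z (cylindrical-lens astigmatism)::

      sigma_x(z) = sigma0 * sqrt(1 + u^2 + A u^3 + B u^4),  u = (z - gamma) / d
      sigma_y(z) = same with u = (z + gamma) / d

  With mirror-symmetric parameters (A = 0) the widths cross at z = 0 and
  sigma_x(z) = sigma_y(-z).

Expected per-pixel photon fractions are the exact integral of the Gaussian
over each unit pixel, computed per axis as a difference of error functions.

Coordinate convention: pixels are unit squares in a 0-based frame; the
center of pixel (row i, column j) is at (x, y) = (j + 0.5, i + 0.5) pixels.
x runs along columns, y along rows; all nm quantities convert through
``pixel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

__all__ = ["PSFModel", "psf_pixel_integrals"]

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class PSFModel:
    """Parametric Gaussian PSF.

    Parameters
    ----------
    kind
        ``"gauss2d"`` or ``"astigmatic3d"``.
    sigma0
        In-focus Gaussian width (std dev), nm.
    pixel_size
        Projected camera pixel width, nm (default 98).
    gamma, d, A, B
        Astigmatism parameters (nm, nm, dimensionless, dimensionless); only
        used for ``astigmatic3d``.  ``gamma`` is the per-axis focal offset,
        ``d`` the depth scale, ``A``/``B`` higher-order corrections.
    """

    kind: str = "gauss2d"
    sigma0: float = 130.0
    pixel_size: float = 98.0
    gamma: float = 250.0
    d: float = 400.0
    A: float = 0.0
    B: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("gauss2d", "astigmatic3d"):
            raise ValueError(f"unknown PSF kind {self.kind!r}")
        if self.sigma0 <= 0 or self.pixel_size <= 0:
            raise ValueError("sigma0 and pixel_size must be > 0")
        if self.kind == "astigmatic3d" and self.d <= 0:
            raise ValueError("depth scale d must be > 0")

    @property
    def n_params(self) -> int:
        """Fit-parameter count: (x, y[, z], N, bg)."""
        return 5 if self.kind == "astigmatic3d" else 4

    def _sigma_axis(self, z: np.ndarray, sign: float) -> tuple[np.ndarray, np.ndarray]:
        """sigma (nm) and d sigma/dz (dimensionless) for one axis."""
        u = (np.asarray(z, dtype=float) + sign * self.gamma) / self.d
        poly = 1.0 + u**2 + self.A * u**3 + self.B * u**4
        if np.any(poly <= 0):
            raise ValueError("astigmatic sigma undefined (poly <= 0) at this z")
        s = self.sigma0 * np.sqrt(poly)
        dpoly = 2.0 * u + 3.0 * self.A * u**2 + 4.0 * self.B * u**3
        ds_dz = self.sigma0 * dpoly / (2.0 * np.sqrt(poly) * self.d)
        return s, ds_dz

    def sigmas_nm(self, z: float | np.ndarray = 0.0) -> tuple[np.ndarray, np.ndarray]:
        """(sigma_x, sigma_y) in nm at axial position z (nm)."""
        if self.kind == "gauss2d":
            z = np.asarray(z, dtype=float)
            s = np.broadcast_to(self.sigma0, z.shape).astype(float)
            return s, s.copy()
        sx, _ = self._sigma_axis(z, -1.0)
        sy, _ = self._sigma_axis(z, +1.0)
        return sx, sy

    def sigmas_and_grads_px(
        self, z: float | np.ndarray = 0.0
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(sigma_x, sigma_y) in pixels and their derivatives w.r.t. z (1/nm)."""
        if self.kind == "gauss2d":
            z = np.asarray(z, dtype=float)
            s = np.broadcast_to(self.sigma0 / self.pixel_size, z.shape).astype(float)
            zero = np.zeros_like(s)
            return s, s.copy(), zero, zero.copy()
        sx, dsx = self._sigma_axis(z, -1.0)
        sy, dsy = self._sigma_axis(z, +1.0)
        p = self.pixel_size
        return sx / p, sy / p, dsx / p, dsy / p


def _axis_integrals(center_px: np.ndarray, sigma_px: np.ndarray, n: int):
    """Per-pixel Gaussian integrals along one axis and their derivatives.

    Parameters are batched: ``center_px`` and ``sigma_px`` have shape (B,).
    Returns (frac, d/dcenter, d/dsigma), each of shape (B, n), where pixel i
    spans [i, i+1) in pixel units.
    """
    center = np.atleast_1d(np.asarray(center_px, dtype=float))[:, None]
    sigma = np.atleast_1d(np.asarray(sigma_px, dtype=float))[:, None]
    edges = np.arange(n + 1, dtype=float)[None, :]
    u = (edges - center) / sigma  # (B, n+1) standardized edge positions
    cdf = 0.5 * (1.0 + erf(u / _SQRT2))
    pdf = _INV_SQRT_2PI * np.exp(-0.5 * u**2)
    frac = cdf[:, 1:] - cdf[:, :-1]
    d_center = (pdf[:, :-1] - pdf[:, 1:]) / sigma
    d_sigma = (u[:, :-1] * pdf[:, :-1] - u[:, 1:] * pdf[:, 1:]) / sigma
    return frac, d_center, d_sigma


def psf_pixel_integrals(
    psf: PSFModel,
    x: float,
    y: float,
    z: float = 0.0,
    roi_shape: tuple[int, int] = (13, 13),
) -> np.ndarray:
    """Expected fractional photon count per ROI pixel for an emitter.

    ``x``/``y``/``z`` are nm; (x, y) must lie inside the ROI.  The result
    sums to at most 1 (exactly 1 minus the tail mass outside the ROI).
    """
    rows, cols = roi_shape
    px = psf.pixel_size
    x_px, y_px = x / px, y / px
    if not (0 <= x_px <= cols and 0 <= y_px <= rows):
        raise ValueError("emitter position outside ROI")
    sx, sy = psf.sigmas_nm(z)
    if np.any(sx <= 0) or np.any(sy <= 0):
        raise ValueError("PSF sigma must be > 0")
    ex, _, _ = _axis_integrals(np.atleast_1d(x_px), np.atleast_1d(sx / px), cols)
    ey, _, _ = _axis_integrals(np.atleast_1d(y_px), np.atleast_1d(sy / px), rows)
    return ey[0][:, None] * ex[0][None, :]
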