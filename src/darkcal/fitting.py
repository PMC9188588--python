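"""Per-pixel-variance-aware Poisson MLE localization and CRLB.

Camera counts are first converted to photoelectron units with the
exposure-time-dependent maps::

    e_k = (ADU_k - offset_k) / photon_response_k
    v_k = variance_k / photon_response_k^2

The Gaussian read+thermal noise of pixel ``k`` (variance ``v_k`` in
electron^2) is folded into a pure Poisson likelihood by the variance-shift
device: effective data ``d_k = e_k + v_k`` and effective model
``m_k(theta) = N*E_k(theta) + bg + v_k`` are treated as Poisson, and

    L(theta) = sum_k d_k * ln m_k - m_k

is maximized over ``theta = (x, y[, z], N, bg)``.  Because ``offset_k``
contains ``dark_current * t`` and ``variance_k`` contains
``thermal_noise^2 * t``, the dark current's mean is removed and its Poisson
variance is counted — this is what makes the correction specific to the
exposure time the maps were derived for.

Optimization is damped Newton (Levenberg-Marquardt on the Fisher-scoring
normal equations) with analytic gradients, vectorized over batches of ROIs
so repeat-heavy simulation studies stay fast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import DerivedMaps
from .psf import PSFModel, _axis_integrals

__all__ = ["FitResult", "mle_fit", "crlb", "fit_roi_batch"]

_M_FLOOR = 1e-6  # floor for the effective model inside the log


@dataclass
class FitResult:
    """Single-ROI fit outcome.  Positions in nm, photons/background in
    photoelectrons; ``crlb`` maps parameter name to its variance lower bound
    (nm^2 for positions) evaluated at the estimate."""

    x: float
    y: float
    z: float | None
    photons: float
    background: float
    log_likelihood: float
    converged: bool
    iterations: int
    crlb: dict[str, float]

    @property
    def estimates(self) -> dict[str, float]:
        out = {"x": self.x, "y": self.y, "photons": self.photons, "background": self.background}
        if self.z is not None:
            out["z"] = self.z
        return out


def _param_names(psf: PSFModel) -> list[str]:
    if psf.n_params == 5:
        return ["x", "y", "z", "photons", "background"]
    return ["x", "y", "photons", "background"]


def _model_and_jac(psf: PSFModel, theta: np.ndarray, roi_shape: tuple[int, int]):
    """Expected photoelectron map and its parameter Jacobian, batched.

    ``theta`` has shape (B, P) with columns [x_px, y_px, (z_nm,) N, bg].
    Returns (mu, jac) of shapes (B, H, W) and (B, P, H, W); mu excludes the
    variance shift.
    """
    rows, cols = roi_shape
    B, P = theta.shape
    x, y = theta[:, 0], theta[:, 1]
    if P == 5:
        z, N, bg = theta[:, 2], theta[:, 3], theta[:, 4]
    else:
        z = np.zeros(B)
        N, bg = theta[:, 2], theta[:, 3]
    sx, sy, dsx_dz, dsy_dz = psf.sigmas_and_grads_px(z)
    ex, dex_dx, dex_dsx = _axis_integrals(x, sx, cols)
    ey, dey_dy, dey_dsy = _axis_integrals(y, sy, rows)

    E = ey[:, :, None] * ex[:, None, :]
    Nc = N[:, None, None]
    mu = Nc * E + bg[:, None, None]

    jac = np.empty((B, P, rows, cols))
    jac[:, 0] = Nc * ey[:, :, None] * dex_dx[:, None, :]
    jac[:, 1] = Nc * dey_dy[:, :, None] * ex[:, None, :]
    if P == 5:
        jac[:, 2] = Nc * (
            ey[:, :, None] * (dex_dsx * dsx_dz[:, None])[:, None, :]
            + (dey_dsy * dsy_dz[:, None])[:, :, None] * ex[:, None, :]
        )
        jac[:, 3] = E
        jac[:, 4] = 1.0
    else:
        jac[:, 2] = E
        jac[:, 3] = 1.0
    return mu, jac


def _bounds(psf: PSFModel, roi_shape: tuple[int, int]):
    rows, cols = roi_shape
    if psf.n_params == 5:
        lo = np.array([0.0, 0.0, -800.0, 1.0, 0.0])
        hi = np.array([cols, rows, 800.0, np.inf, np.inf])
        tol = np.array([1e-4, 1e-4, 1e-2, 1e-2, 1e-3])
    else:
        lo = np.array([0.0, 0.0, 1.0, 0.0])
        hi = np.array([cols, rows, np.inf, np.inf])
        tol = np.array([1e-4, 1e-4, 1e-2, 1e-3])
    return lo, hi, tol


def _init_theta(data_e: np.ndarray, psf: PSFModel, roi_shape: tuple[int, int]) -> np.ndarray:
    """Centroid / quantile initialization in internal (pixel) units."""
    rows, cols = roi_shape
    B = data_e.shape[0]
    bg0 = np.clip(np.quantile(data_e, 0.25, axis=(1, 2)), 0.0, None)
    sig = np.clip(data_e - bg0[:, None, None], 0.0, None)
    tot = sig.sum(axis=(1, 2))
    safe_tot = np.where(tot > 0, tot, 1.0)
    xc = (np.arange(cols) + 0.5)[None, :]
    yc = (np.arange(rows) + 0.5)[None, :]
    x0 = np.where(tot > 0, (sig.sum(axis=1) * xc).sum(axis=1) / safe_tot, cols / 2.0)
    y0 = np.where(tot > 0, (sig.sum(axis=2) * yc).sum(axis=1) / safe_tot, rows / 2.0)
    N0 = np.maximum(tot, 10.0)
    if psf.n_params == 5:
        return np.column_stack([x0, y0, np.zeros(B), N0, bg0])
    return np.column_stack([x0, y0, N0, bg0])


def _loglik(d: np.ndarray, m: np.ndarray) -> np.ndarray:
    return (d * np.log(m) - m).sum(axis=(1, 2))


def _fit_batch(
    data_e: np.ndarray,
    v: np.ndarray,
    psf: PSFModel,
    theta0: np.ndarray | None = None,
    max_iter: int = 50,
):
    """Levenberg-Marquardt over a batch of ROIs.

    ``data_e`` is (B, H, W) photoelectron data, ``v`` the per-pixel Gaussian
    variance in electron^2 ((H, W), (B, H, W) or scalar).  Returns
    (theta (B, P) in internal units, converged (B,), iterations (B,),
    log-likelihood (B,)).
    """
    B, rows, cols = data_e.shape
    roi_shape = (rows, cols)
    v = np.maximum(np.broadcast_to(np.asarray(v, dtype=float), data_e.shape), 0.0)
    d = data_e + v
    lo, hi, tol = _bounds(psf, roi_shape)
    theta = _init_theta(data_e, psf, roi_shape) if theta0 is None else np.array(theta0, dtype=float)
    theta = np.clip(theta, lo, hi)
    P = theta.shape[1]

    mu, jac = _model_and_jac(psf, theta, roi_shape)
    m = np.maximum(mu + v, _M_FLOOR)
    ll = _loglik(d, m)

    lam = np.full(B, 1e-3)
    converged = np.zeros(B, dtype=bool)
    iterations = np.zeros(B, dtype=int)
    active = np.ones(B, dtype=bool)
    eye = np.eye(P)

    for _ in range(max_iter):
        if not active.any():
            break
        ia = np.flatnonzero(active)
        w = 1.0 / m[ia]
        r = d[ia] * w - 1.0
        J = jac[ia]
        g = np.einsum("bphw,bhw->bp", J, r)
        H = np.einsum("bphw,bqhw,bhw->bpq", J, J, w)
        diagH = np.einsum("bpp->bp", H).copy()
        diagH = np.maximum(diagH, 1e-12)
        A = H + lam[ia, None, None] * diagH[:, None, :] * eye[None]
        A += 1e-12 * np.trace(A, axis1=1, axis2=2)[:, None, None] * eye[None]
        try:
            delta = np.linalg.solve(A, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            A += 1e-6 * np.trace(A, axis1=1, axis2=2)[:, None, None] * eye[None]
            delta = np.linalg.solve(A, g[..., None])[..., 0]
        cand = np.clip(theta[ia] + delta, lo, hi)
        mu_c, jac_c = _model_and_jac(psf, cand, roi_shape)
        m_c = np.maximum(mu_c + v[ia], _M_FLOOR)
        ll_c = _loglik(d[ia], m_c)

        better = ll_c >= ll[ia]
        ib = ia[better]
        if ib.size:
            step = np.abs(cand[better] - theta[ib])
            theta[ib] = cand[better]
            mu[ib] = mu_c[better]
            jac[ib] = jac_c[better]
            m[ib] = m_c[better]
            ll[ib] = ll_c[better]
            lam[ib] = np.maximum(lam[ib] / 3.0, 1e-9)
            done = (step < tol).all(axis=1)
            converged[ib[done]] = True
            active[ib[done]] = False
        iw = ia[~better]
        lam[iw] *= 8.0
        stuck = lam > 1e9
        active[stuck] = False
        iterations[active] += 1

    return theta, converged, iterations, ll


def _maps_arrays(maps: DerivedMaps, roi_shape: tuple[int, int], corrected: bool):
    """ROI-shaped (offset, photon_response, v_electron2) from derived maps."""
    offset = np.asarray(maps.offset, dtype=float)
    variance = np.asarray(maps.variance, dtype=float)
    pr = np.asarray(maps.photon_response, dtype=float)
    if not corrected:
        # field-average scalars: ignore pixel-to-pixel variations entirely
        offset = np.full(roi_shape, offset.mean())
        variance = np.full(roi_shape, variance.mean())
        pr = np.full(roi_shape, pr.mean())
    else:
        offset = np.broadcast_to(offset, roi_shape)
        variance = np.broadcast_to(variance, roi_shape)
        pr = np.broadcast_to(pr, roi_shape)
    v = np.maximum(variance, 0.0) / pr**2
    return offset, pr, v


def fit_roi_batch(
    rois_adu: np.ndarray,
    maps: DerivedMaps,
    psf: PSFModel,
    corrected: bool = True,
    theta0: np.ndarray | None = None,
    max_iter: int = 50,
):
    """Fit a batch of ADU ROIs sharing one set of camera maps.

    Returns ``(estimates, converged, iterations, log_likelihood)`` where
    ``estimates`` is a dict of arrays with positions in nm.
    """
    rois_adu = np.asarray(rois_adu, dtype=float)
    if rois_adu.ndim == 2:
        rois_adu = rois_adu[None]
    roi_shape = rois_adu.shape[1:]
    offset, pr, v = _maps_arrays(maps, roi_shape, corrected)
    data_e = (rois_adu - offset) / pr
    theta, conv, iters, ll = _fit_batch(data_e, v, psf, theta0, max_iter)
    p = psf.pixel_size
    est = {"x": theta[:, 0] * p, "y": theta[:, 1] * p}
    if psf.n_params == 5:
        est["z"] = theta[:, 2]
        est["photons"] = theta[:, 3]
        est["background"] = theta[:, 4]
    else:
        est["photons"] = theta[:, 2]
        est["background"] = theta[:, 3]
    return est, conv, iters, ll


def mle_fit(
    roi: np.ndarray,
    maps: DerivedMaps,
    psf: PSFModel,
    init: dict[str, float] | None = None,
    corrected: bool = True,
    max_iter: int = 50,
) -> FitResult:
    """Maximum-likelihood fit of a single emitter ROI.

    ``maps`` must cover the ROI (same shape, or scalars); with
    ``corrected=False`` the per-pixel maps are replaced by their field
    means, reproducing a fitter that neglects pixel-to-pixel variations.
    Non-convergence is reported through ``FitResult.converged``, never as an
    exception.
    """
    roi = np.asarray(roi, dtype=float)
    if not np.all(np.isfinite(roi)):
        raise ValueError("ROI contains non-finite values")
    theta0 = None
    if init is not None:
        p = psf.pixel_size
        row = [init["x"] / p, init["y"] / p]
        if psf.n_params == 5:
            row.append(init.get("z", 0.0))
        row += [init["photons"], init.get("background", 0.0)]
        theta0 = np.array([row])
    est, conv, iters, ll = fit_roi_batch(roi, maps, psf, corrected, theta0, max_iter)
    theta_hat = {k: float(v_[0]) for k, v_ in est.items()}
    try:
        bounds = crlb(psf, theta_hat, maps, roi.shape, corrected=corrected)
    except (ValueError, np.linalg.LinAlgError):
        bounds = {k: float("nan") for k in _param_names(psf)}
    return FitResult(
        x=theta_hat["x"],
        y=theta_hat["y"],
        z=theta_hat.get("z"),
        photons=theta_hat["photons"],
        background=theta_hat["background"],
        log_likelihood=float(ll[0]),
        converged=bool(conv[0]),
        iterations=int(iters[0]),
        crlb=bounds,
    )


def crlb(
    psf: PSFModel,
    theta: dict[str, float],
    maps: DerivedMaps | float | np.ndarray,
    roi_shape: tuple[int, int] = (13, 13),
    corrected: bool = True,
) -> dict[str, float]:
    """Cramér-Rao variance lower bounds at ``theta``.

    The Fisher information of the variance-shifted Poisson model is

        I_ij = sum_k (dmu_k/dtheta_i)(dmu_k/dtheta_j) / (mu_k + v_k)

    with ``mu`` the expected photoelectron map and ``v`` the per-pixel
    Gaussian variance (electron^2).  ``maps`` may be a
    :class:`~darkcal.calibration.DerivedMaps` (``v`` derived from its
    variance and photon response) or a raw ``v`` array/scalar.  Returns the
    diagonal of the inverse Fisher matrix keyed by parameter name; position
    entries are nm^2.
    """
    if isinstance(maps, DerivedMaps):
        _, _, v = _maps_arrays(maps, roi_shape, corrected)
    else:
        v = np.maximum(np.broadcast_to(np.asarray(maps, dtype=float), roi_shape), 0.0)
    p = psf.pixel_size
    row = [theta["x"] / p, theta["y"] / p]
    if psf.n_params == 5:
        row.append(theta.get("z", 0.0))
    row += [theta["photons"], theta.get("background", 0.0)]
    th = np.array([row])
    mu, jac = _model_and_jac(psf, th, roi_shape)
    m = mu[0] + v
    if np.any(m < 0):
        raise ValueError("model + variance must be positive on all pixels")
    m = np.maximum(m, _M_FLOOR)  # same floor as the likelihood
    J = jac[0]
    # express position derivatives per nm
    J = J.copy()
    J[0] /= p
    J[1] /= p
    names = _param_names(psf)
    P = len(names)
    Jf = J.reshape(P, -1)
    I = (Jf / m.ravel()) @ Jf.T
    diag = np.diag(I)
    if np.any(diag <= 0):
        bad = names[int(np.argmin(diag))]
        raise ValueError(f"singular Fisher information: parameter {bad!r} is degenerate")
    # scale-invariant conditioning check: normalize by the diagonal so the
    # mixed parameter units (nm, photons) do not masquerade as singularity
    s = 1.0 / np.sqrt(diag)
    C = I * np.outer(s, s)
    w, V = np.linalg.eigh(C)
    if w[0] <= 0 or w[0] < 1e-12 * w[-1]:
        # name the parameter dominating the null direction
        bad = names[int(np.argmax(np.abs(V[:, 0])))]
        raise ValueError(f"singular Fisher information: parameter {bad!r} is degenerate")
    cov = np.linalg.inv(I)
    return {name: float(cov[i, i]) for i, name in enumerate(names)}
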