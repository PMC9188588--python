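"""MLE localization: likelihood correctness, oracle comparisons, CRLB."""

import numpy as np
import pytest
from scipy.optimize import minimize

import darkcal as dc
from darkcal.calibration import DerivedMaps
from darkcal.fitting import _model_and_jac, crlb, fit_roi_batch, mle_fit
from darkcal.psf import PSFModel, psf_pixel_integrals

PX = 98.0


def ideal_maps(shape, variance=0.0):
    """Maps for an ideal detector: zero offset, unit photon response."""
    return DerivedMaps(
        exposure_time=0.05,
        offset=np.zeros(shape),
        variance=np.full(shape, float(variance)),
        photon_response=np.ones(shape),
    )


def render(psf, x, y, z, photons, background, shape):
    e = psf_pixel_integrals(psf, x, y, z, shape)
    return photons * e + background


class TestMLEFit:
    def test_noise_free_recovery(self):
        psf = PSFModel(sigma0=130.0)
        shape = (13, 13)
        mu = render(psf, 6.3 * PX, 6.8 * PX, 0.0, 5000.0, 10.0, shape)
        res = mle_fit(mu, ideal_maps(shape), psf)
        assert res.converged
        assert res.x / PX == pytest.approx(6.3, abs=1e-3)
        assert res.y / PX == pytest.approx(6.8, abs=1e-3)
        assert res.photons == pytest.approx(5000.0, rel=1e-4)
        assert res.background == pytest.approx(10.0, abs=1e-3)

    def test_noise_free_recovery_3d(self):
        psf = PSFModel(kind="astigmatic3d", sigma0=130.0)
        shape = (15, 15)
        mu = render(psf, 7.5 * PX, 7.2 * PX, 120.0, 8000.0, 20.0, shape)
        res = mle_fit(mu, ideal_maps(shape), psf)
        assert res.converged
        assert res.x / PX == pytest.approx(7.5, abs=1e-3)
        assert res.z == pytest.approx(120.0, abs=1.0)

    def test_optimum_beats_dense_grid_search(self):
        """On 7x7 ROIs the returned optimum's log-likelihood must be at
        least the best over a dense 4-parameter grid."""
        psf = PSFModel(sigma0=130.0)
        shape = (7, 7)
        rng = np.random.default_rng(1)
        maps = ideal_maps(shape, variance=0.0)
        for trial in range(3):
            mu = render(psf, 3.4 * PX, 3.6 * PX, 0.0, 800.0, 5.0, shape)
            roi = rng.poisson(mu).astype(float)
            res = mle_fit(roi, maps, psf)
            best_grid = -np.inf
            # dense grid over x, y, N, bg
            for gx in np.linspace(2.8, 4.2, 11):
                for gy in np.linspace(3.0, 4.4, 11):
                    e = psf_pixel_integrals(psf, gx * PX, gy * PX, 0.0, shape)
                    for gn in np.linspace(500, 1200, 8):
                        for gb in np.linspace(0.0, 12.0, 7):
                            m = np.maximum(gn * e + gb, 1e-6)
                            ll = float((roi * np.log(m) - m).sum())
                            best_grid = max(best_grid, ll)
            assert res.log_likelihood >= best_grid - 1e-9

    def test_reduces_to_standard_poisson_mle_when_v_zero(self):
        """With v=0 the variance-shift likelihood is plain Poisson; an
        independent scipy optimizer must find the same optimum."""
        psf = PSFModel(sigma0=130.0)
        shape = (9, 9)
        rng = np.random.default_rng(7)
        mu = render(psf, 4.4 * PX, 4.7 * PX, 0.0, 2000.0, 8.0, shape)
        roi = rng.poisson(mu).astype(float)
        res = mle_fit(roi, ideal_maps(shape), psf)

        def negll(p):
            x, y, n, b = p
            m = np.maximum(n * psf_pixel_integrals(psf, x, y, 0.0, shape) + b, 1e-6)
            return -(roi * np.log(m) - m).sum()

        ora = minimize(
            negll,
            x0=[res.x, res.y, res.photons, res.background],
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
        )
        assert -ora.fun <= res.log_likelihood + 1e-6
        assert res.x == pytest.approx(ora.x[0], abs=1e-2)
        assert res.y == pytest.approx(ora.x[1], abs=1e-2)

    def test_mirror_symmetry(self):
        """Reflecting ROI and maps must reflect the fitted x."""
        psf = PSFModel(sigma0=130.0)
        shape = (11, 11)
        rng = np.random.default_rng(3)
        v = np.abs(rng.normal(2.0, 0.3, shape))
        mu = render(psf, 4.8 * PX, 5.9 * PX, 0.0, 3000.0, 12.0, shape)
        roi = rng.poisson(mu).astype(float)
        maps = DerivedMaps(0.05, np.zeros(shape), v, np.ones(shape))
        maps_m = DerivedMaps(0.05, np.zeros(shape), v[:, ::-1].copy(), np.ones(shape))
        res = mle_fit(roi, maps, psf)
        res_m = mle_fit(roi[:, ::-1].copy(), maps_m, psf)
        width_nm = shape[1] * PX
        assert res.x + res_m.x == pytest.approx(width_nm, abs=1e-6 * width_nm)
        assert res_m.y == pytest.approx(res.y, abs=1e-6 * width_nm)

    def test_nonconvergence_flagged_not_raised(self):
        psf = PSFModel(sigma0=130.0)
        shape = (9, 9)
        roi = np.zeros(shape)  # no signal at all
        res = mle_fit(roi, ideal_maps(shape), psf, max_iter=2)
        assert isinstance(res.converged, bool)

    def test_nonfinite_roi_rejected(self):
        psf = PSFModel()
        roi = np.full((7, 7), np.nan)
        with pytest.raises(ValueError):
            mle_fit(roi, ideal_maps((7, 7)), psf)


class TestCRLB:
    def test_known_closed_form_limit(self):
        """v=0, bg=0, isolated 2D Gaussian: sqrt-CRLB_x ~ sigma/sqrt(N)."""
        psf = PSFModel(sigma0=130.0)
        theta = {"x": 10.5 * PX, "y": 10.5 * PX, "photons": 5000.0, "background": 0.0}
        b = crlb(psf, theta, 0.0, (21, 21))
        assert np.sqrt(b["x"]) == pytest.approx(130.0 / np.sqrt(5000.0), rel=0.05)

    def test_extra_variance_raises_all_bounds(self):
        psf = PSFModel(kind="astigmatic3d", sigma0=130.0)
        theta = {"x": 6.5 * PX, "y": 6.5 * PX, "z": 50.0, "photons": 3000.0, "background": 10.0}
        b0 = crlb(psf, theta, 0.0, (13, 13))
        b1 = crlb(psf, theta, 4.0, (13, 13))
        for k in b0:
            assert b1[k] > b0[k]

    def test_fisher_matches_finite_differences(self):
        """Analytic Fisher information vs numeric-derivative oracle, 1e-4."""
        psf = PSFModel(kind="astigmatic3d", sigma0=130.0)
        shape = (13, 13)
        v = 3.0
        th = np.array([[6.2, 6.9, 80.0, 4000.0, 12.0]])  # px/px/nm/e-/e-
        mu, jac = _model_and_jac(psf, th, shape)
        m = mu[0] + v

        # numeric Jacobian by central differences in internal units
        steps = [1e-5, 1e-5, 1e-3, 1e-2, 1e-4]
        num = np.empty_like(jac[0])
        for i, h in enumerate(steps):
            tp, tm = th.copy(), th.copy()
            tp[0, i] += h
            tm[0, i] -= h
            num[i] = (_model_and_jac(psf, tp, shape)[0][0] -
                      _model_and_jac(psf, tm, shape)[0][0]) / (2 * h)

        def fisher(J):
            Jf = J.reshape(J.shape[0], -1)
            return (Jf / m.ravel()) @ Jf.T

        fa, fn = fisher(jac[0]), fisher(num)
        np.testing.assert_allclose(fa, fn, rtol=1e-4, atol=1e-10)

    def test_empirical_std_respects_bound(self):
        """No estimator beats the CRLB beyond sampling noise; the MLE
        should also come close to attaining it."""
        psf = PSFModel(sigma0=130.0)
        shape = (13, 13)
        theta = {"x": 6.5 * PX, "y": 6.5 * PX, "photons": 5000.0, "background": 10.0}
        mu = render(psf, theta["x"], theta["y"], 0.0, theta["photons"], theta["background"], shape)
        rng = np.random.default_rng(5)
        stack = rng.poisson(mu, size=(400,) + shape).astype(float)
        est, conv, _, _ = fit_roi_batch(stack, ideal_maps(shape), psf)
        assert conv.mean() > 0.99
        b = crlb(psf, theta, ideal_maps(shape), shape)
        n = stack.shape[0]
        floor = 1.0 - 3.0 / np.sqrt(2 * n)
        for ax in ("x", "y"):
            s = est[ax].std()
            assert s >= np.sqrt(b[ax]) * floor
            assert s <= np.sqrt(b[ax]) * 1.2

    def test_degenerate_parameter_named(self):
        psf = PSFModel(sigma0=130.0)
        theta = {"x": 3.5 * PX, "y": 3.5 * PX, "photons": 1000.0, "background": 0.0}
        # uniform ROI of pure background with N=0-like degeneracy: make the
        # PSF so wide that x/y carry no information
        wide = PSFModel(sigma0=1e6)
        with pytest.raises(ValueError, match="degenerate|singular"):
            crlb(wide, theta, 0.0, (7, 7))
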