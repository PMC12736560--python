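"""Vesselness filter tests against closed forms and brute-force oracles."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d

from tubulemorph.segmentation import (
    VesselnessParams,
    frangi_vesselness,
    global_threshold,
    hessian_eigenvalues,
)


def _derivative_kernel(sigma: float, order: int) -> np.ndarray:
    """Impulse response of the 1D Gaussian-derivative filter."""
    radius = int(8.0 * sigma + 0.5)
    impulse = np.zeros(4 * radius + 1)
    impulse[2 * radius] = 1.0
    resp = gaussian_filter1d(impulse, sigma, order=order, truncate=8.0)
    return resp[radius : 3 * radius + 1]


def bruteforce_hessian_eigenvalues(image: np.ndarray, sigma: float):
    """Independent oracle: explicit 2D convolution + per-pixel eigh.

    Builds the separable derivative kernels from the filter's impulse
    response, convolves with an explicit windowed sum over a mirrored
    image (numpy's "symmetric" padding matches the filter's reflective
    boundary), and diagonalises each 2x2 Hessian with numpy's symmetric
    eigensolver.
    """
    radius = int(8.0 * sigma + 0.5)
    k0 = _derivative_kernel(sigma, 0)
    k1 = _derivative_kernel(sigma, 1)
    k2 = _derivative_kernel(sigma, 2)

    def conv2(img, ky, kx):
        # out = img (x) R where R is the impulse response: correlate with
        # the mirrored kernels
        k2d = ky[::-1][:, None] * kx[::-1][None, :]
        padded = np.pad(img, radius, mode="symmetric")
        ny, nx = img.shape
        w = 2 * radius + 1
        out = np.zeros_like(img, dtype=float)
        for i in range(ny):
            for j in range(nx):
                out[i, j] = float((k2d * padded[i : i + w, j : j + w]).sum())
        return out

    img = np.asarray(image, dtype=float)
    hxx = conv2(img, k0, k2) * sigma**2
    hyy = conv2(img, k2, k0) * sigma**2
    hxy = conv2(img, k1, k1) * sigma**2
    l1 = np.zeros_like(img)
    l2 = np.zeros_like(img)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            w = np.linalg.eigvalsh([[hxx[i, j], hxy[i, j]], [hxy[i, j], hyy[i, j]]])
            a, b = sorted(w, key=abs)
            l1[i, j], l2[i, j] = a, b
    return l1, l2


class TestHessian:
    def test_constant_image_has_zero_eigenvalues(self):
        l1, l2 = hessian_eigenvalues(np.full((16, 16), 3.7), sigma=1.5)
        assert np.allclose(l1, 0) and np.allclose(l2, 0)

    @pytest.mark.parametrize("sigma", [1.0, 2.0])
    def test_quadratic_ramp_matches_analytic_hessian(self, sigma):
        # f(x, y) = y^2 has d2f/dy2 = 2 everywhere; gamma-normalization
        # multiplies by sigma^2
        pad = int(8 * sigma) + 1
        n = 24 + 2 * pad
        img = np.tile((np.arange(n, dtype=float) ** 2)[:, None], (1, n))
        l1, l2 = hessian_eigenvalues(img, sigma)
        interior = slice(pad, n - pad)
        expected = 2.0 * sigma**2
        assert np.allclose(l2[interior, interior], expected, rtol=1e-3)
        assert np.allclose(l1[interior, interior], 0.0, atol=1e-3 * expected)

    @pytest.mark.parametrize("size,sigma,seed", [(8, 1.0, 0), (12, 1.5, 1), (16, 2.0, 2)])
    def test_matches_bruteforce_oracle(self, size, sigma, seed):
        img = np.random.default_rng(seed).uniform(size=(size, size))
        l1, l2 = hessian_eigenvalues(img, sigma)
        o1, o2 = bruteforce_hessian_eigenvalues(img, sigma)
        assert np.allclose(l1, o1, atol=1e-8)
        assert np.allclose(l2, o2, atol=1e-8)

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            hessian_eigenvalues(np.zeros((4, 4)), sigma=0.0)


def _gaussian_ridge(n=64, row=32, sd=1.5, amplitude=10.0):
    y = np.arange(n)[:, None]
    return amplitude * np.exp(-((y - row) ** 2) / (2 * sd**2)) * np.ones((1, n))


class TestFrangi:
    def test_constant_image_gives_zero_vesselness(self):
        v = frangi_vesselness(np.full((32, 32), 5.0), VesselnessParams())
        assert np.all(v == 0)

    def test_ridge_centerline_dominates_background(self):
        img = _gaussian_ridge()
        v = frangi_vesselness(img, VesselnessParams())
        on = v[32, 10:54].mean()
        off = v[[5, 10, 54, 59], 10:54].mean()
        assert on > 10 * max(off, 1e-12)

    def test_ridge_beats_equal_peak_blob(self):
        # blobness ratio Rb ~ 1 suppresses isotropic structures
        n = 64
        y, x = np.mgrid[0:n, 0:n]
        blob = 10.0 * np.exp(-((y - 32) ** 2 + (x - 32) ** 2) / (2 * 1.5**2))
        ridge = _gaussian_ridge()
        params = VesselnessParams()
        v_ridge = frangi_vesselness(ridge, params)[32, 32]
        v_blob = frangi_vesselness(blob, params)[32, 32]
        assert v_ridge > v_blob

    def test_rotation_by_90_degrees_is_exact(self):
        img = np.random.default_rng(3).uniform(size=(24, 24))
        v = frangi_vesselness(img, VesselnessParams())
        v_rot = frangi_vesselness(np.rot90(img), VesselnessParams())
        assert np.allclose(v_rot, np.rot90(v), atol=1e-6)

    def test_intensity_scaling_monotone_with_fixed_c(self):
        img = _gaussian_ridge(amplitude=1.0)
        params = VesselnessParams(c=0.5)
        v1 = frangi_vesselness(img, params)
        v2 = frangi_vesselness(3.0 * img, params)
        assert np.all(v2 >= v1 - 1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            VesselnessParams(sigmas=())
        with pytest.raises(ValueError):
            VesselnessParams(beta=0.0)
        with pytest.raises(ValueError):
            VesselnessParams(c=-1.0)


def exhaustive_otsu(values: np.ndarray) -> float:
    """Oracle: scan every midpoint between sorted unique values and return
    the threshold maximising between-class variance."""
    u = np.unique(values)
    best_t, best_var = u[0], -1.0
    for t in (u[:-1] + u[1:]) / 2:
        lo = values[values < t]
        hi = values[values >= t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0 = lo.size / values.size
        w1 = hi.size / values.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


class TestGlobalThreshold:
    def test_all_zero_field_gives_empty_mask(self):
        m = global_threshold(np.zeros((8, 8)))
        assert not m.mask.any()

    def test_fixed_threshold_separates_two_values(self):
        v = np.array([[0.0, 0.8], [0.8, 0.0]])
        m = global_threshold(v, "fixed:0.4")
        assert np.array_equal(m.mask, v == 0.8)
        assert m.threshold == 0.4

    def test_fixed_threshold_out_of_range_warns(self, caplog):
        with caplog.at_level("WARNING"):
            m = global_threshold(np.array([[0.1, 0.2]]), 5.0)
        assert not m.mask.any()
        assert "outside observed range" in caplog.text

    def test_otsu_matches_exhaustive_oracle_on_bimodal_field(self, rng):
        lo = rng.normal(0.1, 0.02, size=600)
        hi = rng.normal(0.8, 0.05, size=400)
        v = np.concatenate([lo, hi]).reshape(25, 40)
        m = global_threshold(v, "otsu")
        t_oracle = exhaustive_otsu(v.ravel())
        # both thresholds must separate the modes and induce the same mask
        assert lo.max() < m.threshold < hi.min()
        assert lo.max() < t_oracle < hi.min()
        assert np.array_equal(m.mask, v >= t_oracle)
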