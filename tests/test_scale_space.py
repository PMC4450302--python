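import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from angioseed.scale_space import (
    HessianField,
    eigen_decompose,
    gaussian_derivatives,
    gaussian_gradient,
    gaussian_hessian,
)

ALL_ORDERS = [(1, 0), (0, 1), (2, 0), (1, 1), (0, 2)]


class TestGaussianDerivatives:
    def test_constant_image_all_derivatives_vanish(self):
        d = gaussian_derivatives(np.full((24, 31), 5.5), sigma=2.0, orders=ALL_ORDERS)
        for grid in d.values():
            assert np.abs(grid).max() < 1e-12

    def test_quadratic_second_derivative_is_exact(self):
        # f = x^2: smoothing adds a constant, so Ixx = 2 * sigma^2 (normalized)
        xx = np.arange(40, dtype=float) ** 2
        image = np.tile(xx, (40, 1))
        for sigma in (1.0, 2.5):
            d = gaussian_derivatives(image, sigma, orders=[(2, 0), (1, 1), (0, 2)])
            interior = np.s_[15:25, 15:25]
            assert d[(2, 0)][interior] == pytest.approx(2.0 * sigma**2, rel=1e-10)
            assert np.abs(d[(1, 1)][interior]).max() < 1e-9
            assert np.abs(d[(0, 2)][interior]).max() < 1e-9

    def test_gaussian_ridge_crest_matches_closed_form_and_dense_convolution(self):
        # ridge exp(-x^2/(2 s^2)) extruded along y; smoothing at sigma gives
        # combined width w = sqrt(s^2 + sigma^2) and crest curvature -s/w^3,
        # gamma-normalized by sigma^2.  s = sigma = 3 gives -1/(2*sqrt(2)).
        s = sigma = 3.0
        x = np.arange(101, dtype=float) - 50
        ridge = np.exp(-(x**2) / (2 * s**2))
        image = np.tile(ridge, (41, 1))
        ixx = gaussian_hessian(image, sigma).ixx[20, 50]
        closed_form = -sigma**2 * s / (s**2 + sigma**2) ** 1.5
        assert closed_form == pytest.approx(-1.0 / (2.0 * np.sqrt(2.0)))
        # independent oracle: dense convolution with an explicitly sampled
        # second-derivative-of-Gaussian kernel at 6 sigma support
        xs = np.arange(-int(6 * sigma), int(6 * sigma) + 1, dtype=float)
        g2 = (
            (xs**2 - sigma**2)
            / sigma**4
            * np.exp(-(xs**2) / (2 * sigma**2))
            / (np.sqrt(2 * np.pi) * sigma)
        )
        dense_ixx = sigma**2 * np.convolve(ridge, g2, mode="same")[50]
        assert dense_ixx == pytest.approx(closed_form, rel=1e-12)
        # the production kernel truncates at 4 sigma: ~0.4% moment loss
        assert ixx == pytest.approx(dense_ixx, rel=1e-2)

    def test_linearity_in_the_image(self, rng):
        f = rng.normal(size=(20, 20))
        g = rng.normal(size=(20, 20))
        a, b = 2.5, -1.25
        d_comb = gaussian_derivatives(a * f + b * g, 1.5, ALL_ORDERS)
        d_f = gaussian_derivatives(f, 1.5, ALL_ORDERS)
        d_g = gaussian_derivatives(g, 1.5, ALL_ORDERS)
        for k in d_comb:
            np.testing.assert_allclose(d_comb[k], a * d_f[k] + b * d_g[k], atol=1e-10)

    @pytest.mark.parametrize(
        "bad, err",
        [
            (dict(sigma=-1.0), "sigma"),
            (dict(sigma=0.0), "sigma"),
        ],
    )
    def test_nonpositive_sigma_rejected(self, bad, err):
        with pytest.raises(ValueError, match=err):
            gaussian_derivatives(np.zeros((5, 5)), orders=[(1, 0)], **bad)

    def test_tiny_image_rejected(self):
        with pytest.raises(ValueError, match="3x3"):
            gaussian_derivatives(np.zeros((2, 5)), 1.0, [(1, 0)])

    def test_nonfinite_image_rejected(self):
        img = np.zeros((5, 5))
        img[2, 2] = np.nan
        with pytest.raises(ValueError, match="finite"):
            gaussian_derivatives(img, 1.0, [(1, 0)])


def _field(a, b, c):
    """Single-pixel HessianField [[a, b], [b, c]]."""
    one = lambda v: np.array([[float(v)]])
    return HessianField(ixx=one(a), ixy=one(b), iyy=one(c), sigma=1.0)


class TestEigenDecompose:
    def test_diagonal_matrix_both_orderings(self):
        e = eigen_decompose(_field(-3, 0, 1), "algebraic")
        assert e.lam1[0, 0] == -3 and e.lam2[0, 0] == 1
        assert abs(e.v1x[0, 0]) == 1 and e.v1y[0, 0] == 0
        m = eigen_decompose(_field(-3, 0, 1), "magnitude")
        assert m.lam1[0, 0] == 1 and m.lam2[0, 0] == -3
        assert m.v1x[0, 0] == 0 and abs(m.v1y[0, 0]) == 1

    def test_pure_offdiagonal(self):
        e = eigen_decompose(_field(0, 1, 0), "algebraic")
        assert e.lam1[0, 0] == pytest.approx(-1) and e.lam2[0, 0] == pytest.approx(1)
        # v1 parallel to (1, -1)/sqrt(2)
        assert abs(e.v1x[0, 0] * (-1) - e.v1y[0, 0] * 1) < 1e-12
        np.testing.assert_allclose(np.hypot(e.v1x, e.v1y), 1.0, atol=1e-12)

    def test_degenerate_pixels_get_axis_aligned_vectors_and_flag(self):
        e = eigen_decompose(_field(2, 0, 2), "algebraic")
        assert e.degenerate[0, 0]
        assert (abs(e.v1x[0, 0]), abs(e.v1y[0, 0])) in {(1.0, 0.0), (0.0, 1.0)}

    @pytest.mark.parametrize("ordering", ["algebraic", "magnitude"])
    def test_random_fields_match_dense_eigensolver(self, ordering, rng):
        n = 1000
        a, b, c = rng.normal(size=(3, n)) * 10
        h = HessianField(
            ixx=a.reshape(1, n), ixy=b.reshape(1, n), iyy=c.reshape(1, n), sigma=1.0
        )
        e = eigen_decompose(h, ordering)
        mats = np.moveaxis(np.array([[a, b], [b, c]]), -1, 0)
        w = np.linalg.eigvalsh(mats)  # ascending
        if ordering == "algebraic":
            np.testing.assert_allclose(e.lam1.ravel(), w[:, 0], atol=1e-9)
            np.testing.assert_allclose(e.lam2.ravel(), w[:, 1], atol=1e-9)
            assert np.all(e.lam1 <= e.lam2 + 1e-12)
        else:
            assert np.all(np.abs(e.lam1) <= np.abs(e.lam2) + 1e-12)
            np.testing.assert_allclose(
                np.sort(np.abs(np.c_[e.lam1.ravel(), e.lam2.ravel()]), axis=1),
                np.sort(np.abs(w), axis=1),
                atol=1e-9,
            )
        # reconstruction H v = lam v, orthonormality, trace/det identities
        for lam, vx, vy in [(e.lam1, e.v1x, e.v1y), (e.lam2, e.v2x, e.v2y)]:
            rx = a.reshape(1, n) * vx + b.reshape(1, n) * vy - lam * vx
            ry = b.reshape(1, n) * vx + c.reshape(1, n) * vy - lam * vy
            assert np.abs(rx).max() < 1e-9 and np.abs(ry).max() < 1e-9
        np.testing.assert_allclose(e.v1x * e.v2x + e.v1y * e.v2y, 0.0, atol=1e-9)
        np.testing.assert_allclose(e.lam1 + e.lam2, a.reshape(1, n) + c.reshape(1, n), atol=1e-9)
        np.testing.assert_allclose(
            e.lam1 * e.lam2, (a * c - b**2).reshape(1, n), atol=1e-6
        )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a=st.floats(-100, 100),
        b=st.floats(-100, 100),
        c=st.floats(-100, 100),
    )
    def test_reconstruction_property(self, a, b, c):
        e = eigen_decompose(_field(a, b, c), "algebraic")
        H = np.array([[a, b], [b, c]])
        scale = max(1.0, np.abs(H).max())
        for lam, vx, vy in [(e.lam1, e.v1x, e.v1y), (e.lam2, e.v2x, e.v2y)]:
            v = np.array([vx[0, 0], vy[0, 0]])
            assert np.abs(H @ v - lam[0, 0] * v).max() < 1e-9 * scale


class TestRotationEquivariance:
    def test_rot90_rotates_eigenvectors_and_permutes_eigenvalues(self, rng):
        image = rng.normal(size=(32, 32))
        sigma = 1.5
        e = eigen_decompose(gaussian_hessian(image, sigma), "algebraic")
        # np.rot90 maps (x, y) -> (y', x') with y' = x, x' = N-1-y
        rot = np.rot90(image)
        er = eigen_decompose(gaussian_hessian(rot, sigma), "algebraic")
        lam1_back = np.rot90(er.lam1, -1)
        np.testing.assert_allclose(lam1_back, e.lam1, atol=1e-9)
        # eigenvector fields rotate by 90 deg: (vx, vy) -> (-vy, vx), up to sign
        v1x_back = np.rot90(er.v1x, -1)
        v1y_back = np.rot90(er.v1y, -1)
        cross = np.abs(v1x_back * e.v1x + v1y_back * e.v1y)  # |cos| of angle between
        rotated_dot = np.abs(-v1y_back * e.v1x + v1x_back * e.v1y)
        keep = ~(e.degenerate | np.rot90(er.degenerate, -1))
        np.testing.assert_allclose(rotated_dot[keep], 1.0, atol=1e-6)
        np.testing.assert_allclose(cross[keep], 0.0, atol=1e-6)

    def test_gradient_field_shapes_and_finiteness(self, rng):
        g = gaussian_gradient(rng.normal(size=(16, 20)), 1.0)
        assert g.gx.shape == g.gy.shape == (16, 20)
        assert np.all(np.isfinite(g.gx)) and np.all(np.isfinite(g.gy))
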