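import numpy as np
import pytest

from gwdemons import demons
from gwdemons.demons import DemonsConfig, GradientField, demons_force, gradient, register, smooth_field, warp_image
from gwdemons.errors import ConfigError, ShapeError
from gwdemons.fields import DeformationField


def _ramp(h=8, w=8):
    return np.tile(np.arange(w, dtype=float), (h, 1)) / w


class TestGradient:
    def test_constant_image_zero_gradient(self):
        g = gradient(np.full((6, 6), 0.3))
        np.testing.assert_array_equal(g.g_row, 0.0)
        np.testing.assert_array_equal(g.g_col, 0.0)

    def test_column_ramp_unit_col_gradient(self):
        img = np.tile(np.arange(8, dtype=float), (6, 1))
        g = gradient(img)
        np.testing.assert_allclose(g.g_col, 1.0)
        np.testing.assert_allclose(g.g_row, 0.0)

    def test_matches_finite_difference_oracle(self, rng):
        img = rng.random((5, 5))
        g = gradient(img)
        # index-by-index central/one-sided differences
        for r in range(5):
            for c in range(5):
                if 0 < r < 4:
                    exp_r = (img[r + 1, c] - img[r - 1, c]) / 2.0
                elif r == 0:
                    exp_r = img[1, c] - img[0, c]
                else:
                    exp_r = img[4, c] - img[3, c]
                if 0 < c < 4:
                    exp_c = (img[r, c + 1] - img[r, c - 1]) / 2.0
                elif c == 0:
                    exp_c = img[r, 1] - img[r, 0]
                else:
                    exp_c = img[r, 4] - img[r, 3]
                assert g.g_row[r, c] == pytest.approx(exp_r, abs=1e-14)
                assert g.g_col[r, c] == pytest.approx(exp_c, abs=1e-14)

    def test_rejects_one_pixel_wide(self):
        with pytest.raises(ShapeError):
            gradient(np.zeros((5, 1)))


class TestDemonsForce:
    def _setup(self, d, g):
        """One interesting pixel: difference d, fixed gradient (g, 0)."""
        R = np.full((4, 4), 0.5)
        F = R.copy()
        F[2, 2] = 0.5 - d
        gr = np.zeros((4, 4))
        gr[2, 2] = g
        gradR = GradientField(gr, np.zeros((4, 4)))
        gradF = GradientField(np.zeros((4, 4)), np.zeros((4, 4)))
        return R, F, gradR, gradF

    @pytest.mark.parametrize("variant", demons.VARIANTS)
    def test_identical_images_zero_force(self, variant, rng):
        img = rng.random((8, 8))
        g = gradient(img)
        f = demons_force(img, img, g, g, DemonsConfig(variant=variant))
        np.testing.assert_array_equal(f.u_row, 0.0)
        np.testing.assert_array_equal(f.u_col, 0.0)

    def test_thirion_single_pixel_hand_value(self):
        d, g = 0.2, 0.4
        R, F, gradR, gradF = self._setup(d, g)
        f = demons_force(R, F, gradR, gradF, DemonsConfig(variant="thirion"))
        assert f.u_row[2, 2] == pytest.approx(d * g / (g**2 + d**2), rel=1e-14)
        assert f.u_col[2, 2] == 0.0
        # all other pixels flat and matched -> zero
        mask = np.ones((4, 4), bool)
        mask[2, 2] = False
        assert np.all(f.u_row[mask] == 0.0)

    def test_wang_single_pixel_hand_value(self):
        d, g = 0.2, 0.4
        alpha = 2.5
        R, F, gradR, gradF = self._setup(d, g)
        # symmetric: give the moving image a gradient too
        gradF = GradientField(gradR.g_row * 0.5, gradR.g_col)
        f = demons_force(R, F, gradR, gradF, DemonsConfig(variant="wang", alpha=alpha))
        expect = d * g / (g**2 + alpha**2 * d**2) + d * (0.5 * g) / (
            (0.5 * g) ** 2 + alpha**2 * d**2
        )
        assert f.u_row[2, 2] == pytest.approx(expect, rel=1e-14)

    def test_wang_force_vanishes_as_alpha_grows(self, rng):
        R = rng.random((6, 6))
        F = rng.random((6, 6))
        gR, gF = gradient(R), gradient(F)
        f = demons_force(R, F, gR, gF, DemonsConfig(variant="wang", alpha=1e8))
        assert np.abs(f.u_row).max() < 1e-12
        assert np.abs(f.u_col).max() < 1e-12

    def test_tang_k1_equals_wang(self, rng):
        R = rng.random((7, 7))
        F = rng.random((7, 7))
        gR, gF = gradient(R), gradient(F)
        fw = demons_force(R, F, gR, gF, DemonsConfig(variant="wang"))
        ft = demons_force(R, F, gR, gF, DemonsConfig(variant="tang", balance_k=1.0))
        np.testing.assert_allclose(ft.u_row, fw.u_row, atol=1e-14)
        np.testing.assert_allclose(ft.u_col, fw.u_col, atol=1e-14)

    def test_shape_mismatch_raises(self, rng):
        R = rng.random((6, 6))
        F = rng.random((5, 6))
        with pytest.raises(ShapeError):
            demons_force(R, F, gradient(R), gradient(F), DemonsConfig())


class TestSmoothField:
    def test_constant_field_unchanged(self):
        f = DeformationField(np.full((20, 20), 2.0), np.full((20, 20), -1.0))
        s = smooth_field(f, (7, 7), 3.0)
        np.testing.assert_allclose(s.u_row, 2.0, atol=1e-12)
        np.testing.assert_allclose(s.u_col, -1.0, atol=1e-12)

    def test_impulse_flat_kernel_limit(self):
        # huge sigma over a 3x3 window -> effectively a 1/9 box filter
        u = np.zeros((9, 9))
        u[4, 4] = 1.0
        s = smooth_field(DeformationField(u, np.zeros_like(u)), (3, 3), 1e6)
        np.testing.assert_allclose(s.u_row[3:6, 3:6], 1.0 / 9.0, atol=1e-9)
        assert s.u_row[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_2d_convolution_oracle(self, rng):
        from scipy import ndimage as ndi

        u = rng.normal(size=(12, 12))
        f = DeformationField(u, u[::-1])
        k1, k2, sigma = 5, 3, 1.7
        x1 = np.arange(k1) - (k1 - 1) / 2.0
        x2 = np.arange(k2) - (k2 - 1) / 2.0
        kern = np.exp(-0.5 * (x1[:, None] / sigma) ** 2) * np.exp(-0.5 * (x2[None, :] / sigma) ** 2)
        kern /= kern.sum()
        expect = ndi.correlate(u, kern, mode="nearest")
        got = smooth_field(f, (k1, k2), sigma)
        np.testing.assert_allclose(got.u_row, expect, atol=1e-12)

    def test_sigma_zero_is_identity(self, rng):
        u = rng.normal(size=(8, 8))
        f = DeformationField(u, -u)
        s = smooth_field(f, (5, 5), 0.0)
        assert s is f

    def test_oversized_window_rejected(self):
        f = DeformationField.zeros((16, 16))
        with pytest.raises(ConfigError):
            smooth_field(f, (300, 3), 2.0)


class TestWarpImage:
    def test_zero_field_identity(self, rng):
        img = rng.random((10, 10))
        out = warp_image(img, DeformationField.zeros((10, 10)))
        np.testing.assert_array_equal(out, img)

    def test_uniform_column_shift_on_ramp(self):
        # out(p) = F(p + u); u_col = -1 samples one column to the left
        img = np.tile(np.arange(8, dtype=float), (8, 1)) / 8.0
        f = DeformationField(np.zeros((8, 8)), np.full((8, 8), -1.0))
        out = warp_image(img, f)
        np.testing.assert_allclose(out[:, 1:], img[:, :-1], atol=1e-12)
        # column 0 samples off the left edge -> clamped to border value
        np.testing.assert_allclose(out[:, 0], img[:, 0], atol=1e-12)

    def test_half_pixel_shift_bilinear_midpoint(self):
        img = np.zeros((4, 6))
        img[:, 3:] = 1.0
        f = DeformationField(np.zeros((4, 6)), np.full((4, 6), 0.5))
        out = warp_image(img, f)
        # pixel at col 2 samples 2.5 -> average of 0 and 1
        np.testing.assert_allclose(out[:, 2], 0.5, atol=1e-12)

    def test_matches_bilinear_oracle(self, rng):
        img = rng.random((7, 7))
        f = DeformationField(rng.uniform(-1.5, 1.5, (7, 7)), rng.uniform(-1.5, 1.5, (7, 7)))
        out = warp_image(img, f)
        for r in range(7):
            for c in range(7):
                sr = min(max(r + f.u_row[r, c], 0.0), 6.0)
                sc = min(max(c + f.u_col[r, c], 0.0), 6.0)
                r0, c0 = int(np.floor(sr)), int(np.floor(sc))
                r1, c1 = min(r0 + 1, 6), min(c0 + 1, 6)
                fr, fc = sr - r0, sc - c0
                expect = (
                    img[r0, c0] * (1 - fr) * (1 - fc)
                    + img[r1, c0] * fr * (1 - fc)
                    + img[r0, c1] * (1 - fr) * fc
                    + img[r1, c1] * fr * fc
                )
                assert out[r, c] == pytest.approx(expect, abs=1e-10)

    def test_nonfinite_field_rejected(self, rng):
        img = rng.random((5, 5))
        u = np.zeros((5, 5))
        u[0, 0] = np.inf
        with pytest.raises(ValueError):
            warp_image(img, DeformationField(u, np.zeros((5, 5))))

    def test_small_field_small_change(self, rng):
        # identity limit: max|u| -> 0 forces the warp toward the identity
        img = rng.random((16, 16))
        for eps in (1e-2, 1e-4, 1e-6):
            f = DeformationField(np.full((16, 16), eps), np.full((16, 16), -eps))
            assert np.abs(warp_image(img, f) - img).max() < 4 * eps


class TestRegister:
    def test_self_registration_is_inert(self, rng):
        img = rng.random((32, 32))
        res = register(img, img, DemonsConfig(n_iterations=10))
        assert res.field.max_abs() < 1e-12
        assert all(c == pytest.approx(1.0, abs=1e-12) for c in res.fitness_history)

    def test_histories_have_iteration_length(self, translation_pair):
        fixed, moving, _ = translation_pair
        res = register(fixed, moving, DemonsConfig(n_iterations=5))
        assert len(res.fitness_history) == 5
        assert len(res.objective_history) == 5
        assert res.warped.shape == fixed.shape

    def test_single_iteration_matches_manual_composition(self, translation_pair):
        fixed, moving, _ = translation_pair
        cfg = DemonsConfig(variant="wang", n_iterations=1)
        res = register(fixed, moving, cfg)
        gR = gradient(fixed)
        du = demons_force(fixed, moving, gR, gradient(moving), cfg)
        u = smooth_field(du, cfg.window, cfg.sigma)
        warped = warp_image(moving, u)
        np.testing.assert_array_equal(res.field.u_row, u.u_row)
        np.testing.assert_array_equal(res.field.u_col, u.u_col)
        np.testing.assert_array_equal(res.warped, warped)

    def test_translation_improves_correlation(self, translation_pair):
        from gwdemons.metrics import correlation

        fixed, moving, _ = translation_pair
        res = register(fixed, moving, DemonsConfig(variant="wang", n_iterations=30))
        assert res.final_correlation > correlation(fixed, moving)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ShapeError):
            register(rng.random((8, 8)), rng.random((8, 9)))

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            DemonsConfig(variant="nope")
        with pytest.raises(ConfigError):
            DemonsConfig(sigma=-1)
        with pytest.raises(ConfigError):
            DemonsConfig(n_iterations=0)
        with pytest.raises(ConfigError):
            DemonsConfig(window=(0, 5))
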