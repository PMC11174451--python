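"""Bilinear and edge-directed interpolation: hand traces, least-squares
oracles, parameter recovery and the hybrid dispatch contract."""

import numpy as np
import pytest

from sicmtools import (
    EdgeMap,
    GrayImage,
    bilinear_upscale,
    enhance_n,
    height_to_gray,
    hybrid_upscale,
    make_edge_scene,
    nedi_coefficients,
    nedi_upscale,
    ssim,
)
from sicmtools.interp import NEDIConfig, _bilinear_float

EXACT_CFG = NEDIConfig(ridge_epsilon=0.0, condition_limit=np.inf)


def separable_mode_image(alpha, shape, ys=(1.2, 1.5), seed=0):
    """An image exactly satisfying the diagonal-neighbor relation
    ``I(p, q) = sum alpha_k * I(p +- 1, q +- 1)`` (NW, NE, SW, SE order).

    Superposes separable modes x**p * y**q: for each y the relation reduces
    to a quadratic in x; both roots are used, giving four independent modes
    whose random seeded mixture is a well-conditioned training image.
    """
    a_nw, a_ne, a_sw, a_se = alpha
    modes = []
    for y in ys:
        c2 = a_sw / y + a_se * y
        c0 = a_nw / y + a_ne * y
        disc = 1.0 - 4.0 * c2 * c0
        assert disc > 0, "chosen y values must give real modes"
        for x in ((1 + np.sqrt(disc)) / (2 * c2), (1 - np.sqrt(disc)) / (2 * c2)):
            modes.append((x, y))
    coef = np.random.default_rng(seed).uniform(0.5, 2.0, len(modes))
    P, Q = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return sum(c * x**P * y**Q for c, (x, y) in zip(coef, modes))


def loop_oracle_alpha(patch, site, m=5):
    """Independent dense normal-equation solve: each window pixel predicted
    from its four diagonal neighbors, built with explicit loops."""
    i, j = site
    C, y = [], []
    for p in range(i - m // 2, i + m // 2 + 1):
        for q in range(j - m // 2, j + m // 2 + 1):
            y.append(patch[p, q])
            C.append([patch[p - 1, q - 1], patch[p - 1, q + 1],
                      patch[p + 1, q - 1], patch[p + 1, q + 1]])
    C, y = np.asarray(C, float), np.asarray(y, float)
    return np.linalg.lstsq(C, y, rcond=None)[0], np.linalg.cond(C.T @ C)


class TestBilinear:
    def test_hand_trace_2x2(self):
        out = bilinear_upscale(GrayImage(np.array([[0, 2], [4, 6]])))
        assert out.pixels.tolist() == [
            [0, 1, 2, 2],
            [2, 3, 4, 4],
            [4, 5, 6, 6],
            [4, 5, 6, 6],
        ]

    def test_constant(self):
        out = bilinear_upscale(GrayImage(np.full((5, 3), 9)))
        assert out.shape == (10, 6) and (out.pixels == 9).all()

    def test_midpoint_average(self):
        out = _bilinear_float(np.array([[0.0, 2.0]]))
        assert out[0, 1] == 1.0

    def test_exact_on_linear_ramp(self):
        ramp = np.add.outer(np.arange(0, 64, 8), np.arange(0, 64, 8))
        hr = _bilinear_float(ramp.astype(float))
        # interior of the HR lattice is the same plane at half step
        exp = np.add.outer(np.arange(0, 64, 4), np.arange(0, 64, 4)).astype(float)
        np.testing.assert_allclose(hr[:-1, :-1], exp[:-1, :-1])

    def test_lr_pixels_on_even_lattice(self, rng):
        px = rng.integers(0, 256, (6, 7))
        out = bilinear_upscale(GrayImage(px))
        np.testing.assert_array_equal(out.pixels[::2, ::2], px)


class TestNEDICoefficients:
    def test_recovers_known_alpha(self):
        alpha_star = np.array([0.4, 0.1, 0.3, 0.2])
        img = separable_mode_image(alpha_star, (11, 11))
        co = nedi_coefficients(img, (5, 5), EXACT_CFG)
        np.testing.assert_allclose(co.alpha, alpha_star, atol=1e-6)

    def test_weighted_sum_reproduces_generated_pixels(self):
        # explicit hand-coded diagonal weighted sum on the generated image
        alpha_star = np.array([0.4, 0.1, 0.3, 0.2])
        img = separable_mode_image(alpha_star, (9, 9))
        for p in range(1, 8):
            for q in range(1, 8):
                pred = (alpha_star[0] * img[p - 1, q - 1]
                        + alpha_star[1] * img[p - 1, q + 1]
                        + alpha_star[2] * img[p + 1, q - 1]
                        + alpha_star[3] * img[p + 1, q + 1])
                assert img[p, q] == pytest.approx(pred, rel=1e-9)

    def test_matches_normal_equation_oracle(self, rng):
        checked = 0
        while checked < 200:
            patch = rng.uniform(0, 255, (9, 9))
            oracle, cond = loop_oracle_alpha(patch, (4, 4))
            if cond > 1e6:
                continue
            co = nedi_coefficients(patch, (4, 4), EXACT_CFG)
            np.testing.assert_allclose(co.alpha, oracle, atol=1e-9)
            checked += 1

    def test_constant_patch_signals_fallback(self):
        assert nedi_coefficients(np.full((9, 9), 55.0), (4, 4)) is None

    def test_border_window_signals_fallback(self, rng):
        patch = rng.uniform(0, 255, (9, 9))
        assert nedi_coefficients(patch, (1, 4)) is None

    def test_sum_to_one_on_planar_patch(self):
        # exact plane: many exact-fit solutions; the ridge-stabilized solve
        # must still land on a convex-combination-like solution
        plane = np.add.outer(np.arange(11) * 7.0, np.arange(11) * 4.0) + 30.0
        cfg = NEDIConfig(ridge_epsilon=1e-8, condition_limit=np.inf)
        co = nedi_coefficients(plane, (5, 5), cfg)
        assert abs(co.alpha.sum() - 1.0) <= 1e-6


class TestNEDIUpscale:
    def test_constant(self):
        out = nedi_upscale(GrayImage(np.full((16, 16), 77)))
        assert out.shape == (32, 32) and (out.pixels == 77).all()

    def test_planar_ramp_within_one_level(self):
        ramp = np.clip(np.add.outer(np.arange(16), np.arange(16)) * 8, 0, 255)
        out = nedi_upscale(GrayImage(ramp)).pixels.astype(float)
        plane = _bilinear_float(ramp.astype(float))  # the exact HR plane
        assert np.abs(out - plane).max() <= 1.0

    def test_diagonal_step_at_least_as_sharp_as_bilinear(self):
        n = 16
        diag = np.where(np.add.outer(np.arange(n), np.arange(n)) < n, 40, 210)
        nu = nedi_upscale(GrayImage(diag)).pixels.astype(float)
        bu = bilinear_upscale(GrayImage(diag)).pixels.astype(float)

        def max_grad(a):
            return max(np.abs(np.diff(a, axis=0)).max(),
                       np.abs(np.diff(a, axis=1)).max())

        assert max_grad(nu) >= max_grad(bu)


class TestHybridDispatch:
    def test_empty_edge_map_is_bilinear_bit_exact(self, rng):
        img = GrayImage(rng.integers(0, 256, (16, 16)))
        empty = EdgeMap(np.zeros((32, 32), bool), resolution_factor=2)
        np.testing.assert_array_equal(
            hybrid_upscale(img, empty).pixels, bilinear_upscale(img).pixels
        )

    def test_full_edge_map_no_cleanup_is_nedi(self, rng):
        img = GrayImage(rng.integers(0, 256, (16, 16)))
        full = EdgeMap(np.ones((32, 32), bool), resolution_factor=2)
        np.testing.assert_array_equal(
            hybrid_upscale(img, full, cleanup="off").pixels,
            nedi_upscale(img).pixels,
        )

    def test_lattice_contract(self, rng):
        img = GrayImage(rng.integers(0, 256, (12, 12)))
        mask = np.zeros((24, 24), bool)
        mask[8:16, 8:16] = True
        out = hybrid_upscale(img, EdgeMap(mask, resolution_factor=2), cleanup="off")
        assert out.shape == (24, 24)
        np.testing.assert_array_equal(out.pixels[::2, ::2], img.pixels)

    def test_shape_mismatch_rejected(self, rng):
        img = GrayImage(rng.integers(0, 256, (12, 12)))
        with pytest.raises(ValueError):
            hybrid_upscale(img, EdgeMap(np.zeros((12, 12), bool), resolution_factor=2))

    def test_downsample_enhance_beats_bilinear_on_edges(self):
        # geometric-duality payoff: on a scene with sharp step edges the
        # edge-gated pipeline recovers the fine rendering better than plain
        # bilinear interpolation
        from sicmtools import canny_edges, upscale_edge_map

        hr = height_to_gray(make_edge_scene((48, 48), (0, 30), seed=3, oversample=2),
                            8, (0, 30))
        lr = GrayImage(hr.pixels[::2, ::2], h_min=0.0, h_max=30.0)
        edges_hr = upscale_edge_map(canny_edges(lr), 2, 1)
        hyb = hybrid_upscale(lr, edges_hr)
        bil = bilinear_upscale(lr)
        assert ssim(hyb, hr) >= ssim(bil, hr)


class TestEnhanceN:
    def test_identity_at_zero(self, clean_gray48):
        out = enhance_n(clean_gray48, 0)
        np.testing.assert_array_equal(out.pixels, clean_gray48.pixels)

    def test_single_iteration_matches_pipeline_stages(self, clean_gray48):
        from sicmtools import canny_edges, upscale_edge_map
        from sicmtools.denoise import FilterSpec, denoise_image
        from sicmtools.edges import CannyConfig

        den = denoise_image(clean_gray48, FilterSpec())
        ehr = upscale_edge_map(canny_edges(den, CannyConfig()), 2, 1)
        expected = hybrid_upscale(den, ehr)
        out = enhance_n(clean_gray48, 1)
        np.testing.assert_array_equal(out.pixels, expected.pixels)

    def test_shape_doubles_per_iteration(self, clean_gray48):
        assert enhance_n(clean_gray48, 2).shape == (192, 192)

    def test_negative_rejected(self, clean_gray48):
        with pytest.raises(ValueError):
            enhance_n(clean_gray48, -1)
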