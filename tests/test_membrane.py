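"""Membrane interpolation: boundary extraction, the direct Shepard
evaluator, the convolution pyramid, and their mutual agreement."""

import numpy as np
import pytest

from bstdmar.membrane import (
    PyramidFilters,
    convpyr_convolve,
    exact_weight_convolve,
    extract_boundary,
    fit_filters,
    membrane_interpolate,
    shepard_direct,
)

from conftest import random_blob_mask, smooth_field


def brute_force_boundary(mask: np.ndarray) -> np.ndarray:
    """Independent 8-neighbor enumeration of the exterior ring."""
    ny, nx = mask.shape
    ring = np.zeros_like(mask, dtype=bool)
    for y in range(ny):
        for x in range(nx):
            if mask[y, x]:
                continue
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    yy, xx = y + dy, x + dx
                    if (dy or dx) and 0 <= yy < ny and 0 <= xx < nx and mask[yy, xx]:
                        ring[y, x] = True
    return ring


class TestExtractBoundary:
    def test_center_pixel_has_eight_neighbors(self):
        f = np.arange(25.0).reshape(5, 5)
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        bext = extract_boundary(f, mask)
        assert bext.chi.sum() == 8
        assert np.array_equal(bext.r_hat[bext.chi], f[bext.chi])
        assert np.all(bext.r_hat[~bext.chi] == 0)

    def test_block_ring_matches_brute_force(self):
        rng = np.random.default_rng(7)
        f = rng.uniform(size=(7, 7))
        mask = np.zeros((7, 7), bool)
        mask[2:5, 2:5] = True
        bext = extract_boundary(f, mask)
        assert bext.chi.sum() == 16
        assert np.array_equal(bext.chi, brute_force_boundary(mask))

    @pytest.mark.parametrize("seed", range(4))
    def test_random_masks_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        mask = random_blob_mask(rng, (32, 32), margin=8)
        f = smooth_field(rng, (32, 32))
        bext = extract_boundary(f, mask)
        assert np.array_equal(bext.chi, brute_force_boundary(mask))

    def test_degenerate_masks_error(self):
        f = np.ones((5, 5))
        with pytest.raises(ValueError):
            extract_boundary(f, np.zeros((5, 5), bool))
        with pytest.raises(ValueError):
            extract_boundary(f, np.ones((5, 5), bool))


class TestShepardDirect:
    def test_constant_boundary_fills_constant(self):
        f = np.full((9, 9), 3.25)
        mask = np.zeros((9, 9), bool)
        mask[3:6, 3:6] = True
        res = shepard_direct(extract_boundary(f, mask), mask)
        assert np.allclose(res.values[mask], 3.25)

    def test_equidistant_pair_averages(self):
        # boundary reduced to two pixels with values 0 and 10; the midpoint
        # between them interpolates to exactly 5
        from bstdmar.membrane import BoundaryExtension

        chi = np.zeros((5, 5), bool)
        chi[2, 0] = chi[2, 4] = True
        r_hat = np.zeros((5, 5))
        r_hat[2, 4] = 10.0
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        res = shepard_direct(BoundaryExtension(r_hat=r_hat, chi=chi), mask)
        assert res.values[2, 2] == pytest.approx(5.0, abs=1e-12)

    def test_matches_double_loop_reimplementation(self):
        rng = np.random.default_rng(11)
        f = rng.uniform(size=(16, 16))
        mask = np.zeros((16, 16), bool)
        mask[5:11, 4:12] = True
        bext = extract_boundary(f, mask)
        res = shepard_direct(bext, mask)
        by, bx = np.nonzero(bext.chi)
        for y, x in zip(*np.nonzero(mask)):
            num = den = 0.0
            for yb, xb, b in zip(by, bx, f[bext.chi]):
                w = ((yb - y) ** 2 + (xb - x) ** 2) ** -1.5
                num += w * b
                den += w
            assert res.values[y, x] == pytest.approx(num / den, abs=1e-12)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(3)
        f = smooth_field(rng, (40, 40))
        mask = random_blob_mask(rng, (40, 40), margin=10)
        res = shepard_direct(extract_boundary(f, mask), mask)
        fs = np.roll(f, (2, 3), axis=(0, 1))
        ms = np.roll(mask, (2, 3), axis=(0, 1))
        res_s = shepard_direct(extract_boundary(fs, ms), ms)
        assert np.allclose(
            res_s.values[ms], np.roll(res.values, (2, 3), axis=(0, 1))[ms], atol=1e-12
        )

    def test_convex_combination_bound(self):
        rng = np.random.default_rng(5)
        f = rng.uniform(size=(32, 32))
        mask = random_blob_mask(rng, (32, 32), margin=8)
        bext = extract_boundary(f, mask)
        res = shepard_direct(bext, mask)
        b = f[bext.chi]
        assert res.values[mask].min() >= b.min() - 1e-12
        assert res.values[mask].max() <= b.max() + 1e-12


class TestConvpyr:
    def test_zero_input_zero_output(self, filters):
        assert np.all(convpyr_convolve(np.zeros((32, 32)), filters) == 0)

    def test_homogeneity(self, filters):
        rng = np.random.default_rng(0)
        x = rng.uniform(size=(48, 48))
        a = convpyr_convolve(3.5 * x, filters)
        b = 3.5 * convpyr_convolve(x, filters)
        assert np.allclose(a, b, rtol=1e-12, atol=1e-12)

    def test_impulse_matches_exact_kernel(self, filters):
        x = np.zeros((64, 64))
        x[32, 32] = 1.0
        approx = convpyr_convolve(x, filters)
        exact = exact_weight_convolve(x)
        off = x == 0
        rel = np.linalg.norm((approx - exact)[off]) / np.linalg.norm(exact[off])
        assert rel <= 0.05

    def test_small_image_reduces_levels(self, filters):
        # deeper than the image allows: must shrink rather than fail
        out = convpyr_convolve(np.ones((8, 8)), PyramidFilters(
            h1=filters.h1, h2=filters.h2, g=filters.g, n_levels=6))
        assert out.shape == (8, 8)
        assert np.all(np.isfinite(out))


class TestFitFilters:
    def test_refit_is_deterministic(self):
        kw = dict(training_size=32, n_images=3, seed=4, tol=0.2)
        f1 = fit_filters(**kw)
        f2 = fit_filters(**kw)
        assert np.array_equal(f1.h1, f2.h1)
        assert np.array_equal(f1.h2, f2.h2)
        assert np.array_equal(f1.g, f2.g)

    def test_training_error_within_tolerance(self, filters):
        rng = np.random.default_rng(123)
        x = np.zeros((64, 64))
        idx = rng.choice(64 * 64, size=40, replace=False)
        x.flat[idx] = rng.uniform(0.1, 1.0, size=40)
        approx = convpyr_convolve(x, filters)
        exact = exact_weight_convolve(x)
        off = x == 0
        rel = np.linalg.norm((approx - exact)[off]) / np.linalg.norm(exact[off])
        assert rel <= 0.05

    def test_larger_exponent_concentrates_response(self):
        # steeper weight decay -> impulse response mass concentrates near
        # the source (smaller normalized second moment)
        spreads = {}
        for p in (2.0, 4.0):
            filt = fit_filters(weight_exponent=p, training_size=32, n_images=3, seed=4, tol=0.35)
            x = np.zeros((64, 64))
            x[32, 32] = 1.0
            resp = np.abs(convpyr_convolve(x, filt))
            yy, xx = np.mgrid[:64, :64]
            d2 = (yy - 32.0) ** 2 + (xx - 32.0) ** 2
            spreads[p] = float((resp * d2).sum() / resp.sum())
        assert spreads[4.0] < spreads[2.0]

    def test_invalid_exponent(self):
        with pytest.raises(ValueError):
            fit_filters(weight_exponent=0)


class TestMembraneInterpolate:
    def test_constant_boundary(self, filters):
        f = np.full((40, 40), 0.7)
        mask = np.zeros((40, 40), bool)
        mask[15:25, 15:25] = True
        res = membrane_interpolate(f, mask, filters)
        assert np.allclose(res.values[mask], 0.7, rtol=1e-6)

    def test_identity_outside_mask(self, filters):
        rng = np.random.default_rng(2)
        f = smooth_field(rng, (64, 64))
        mask = random_blob_mask(rng, (64, 64))
        res = membrane_interpolate(f, mask, filters)
        assert np.array_equal(res.values[~mask], f[~mask])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_shepard(self, filters, seed):
        rng = np.random.default_rng(seed)
        f = smooth_field(rng, (64, 64))
        mask = random_blob_mask(rng, (64, 64))
        bext = extract_boundary(f, mask)
        direct = shepard_direct(bext, mask)
        pyr = membrane_interpolate(f, mask, filters)
        b = f[bext.chi]
        dev = np.mean(np.abs(pyr.values[mask] - direct.values[mask])) / (b.max() - b.min())
        assert dev <= 0.02

    def test_disconnected_blobs_share_global_boundary(self, filters):
        rng = np.random.default_rng(9)
        f = smooth_field(rng, (64, 64))
        mask = np.zeros((64, 64), bool)
        yy, xx = np.mgrid[:64, :64]
        mask |= (yy - 20) ** 2 + (xx - 18) ** 2 < 7**2
        mask |= (yy - 44) ** 2 + (xx - 46) ** 2 < 8**2
        bext = extract_boundary(f, mask)
        direct = shepard_direct(bext, mask)
        pyr = membrane_interpolate(f, mask, filters)
        b = f[bext.chi]
        dev = np.mean(np.abs(pyr.values[mask] - direct.values[mask])) / (b.max() - b.min())
        assert dev <= 0.02
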