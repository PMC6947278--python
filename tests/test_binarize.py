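"""Dual-binarization chain: quality filter, filters, thresholds, masks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import octaquant as oq
from octaquant.binarize import DegenerateInputError, ParameterError
from octaquant.image import EnFaceImage


def img(arr, **kw):
    return EnFaceImage(np.asarray(arr, float), **kw)


def flat_image(n=64, level=0.5):
    return img(np.full((n, n), level))


# ---------------------------------------------------------------------------
# quality filter

class TestQualityFilter:
    def test_drops_scans_below_cutoff(self):
        ims = [flat_image(), flat_image(), flat_image()]
        ims[0].ssi, ims[1].ssi, ims[2].ssi = 9.2, 7.9, 8.0
        kept = oq.quality_filter(ims, 8.0)
        assert [i.ssi for i in kept] == [9.2, 8.0]

    @pytest.mark.parametrize("ssi,expect_n", [(10.0, 4), (0.0, 0)])
    def test_identity_and_empty_extremes(self, ssi, expect_n):
        ims = [flat_image() for _ in range(4)]
        for i in ims:
            i.ssi = ssi
        assert len(oq.quality_filter(ims, 8.0)) == expect_n

    @given(st.lists(st.floats(0, 10), max_size=20),
           st.floats(0, 10), st.floats(0, 10))
    @settings(max_examples=50, deadline=None)
    def test_raising_cutoff_never_keeps_more(self, ssis, lo, hi):
        lo, hi = min(lo, hi), max(lo, hi)
        ims = []
        for s in ssis:
            im = flat_image(8)
            im.ssi = s
            ims.append(im)
        assert len(oq.quality_filter(ims, hi)) <= len(oq.quality_filter(ims, lo))


# ---------------------------------------------------------------------------
# top-hat

class TestTopHat:
    def test_constant_image_maps_to_zero(self):
        out = oq.top_hat(flat_image(), 5)
        assert np.allclose(out.pixels, 0.0)

    def test_single_bright_dot_preserved(self):
        a = np.zeros((40, 40))
        a[20, 20] = 1.0
        out = oq.top_hat(img(a), 5)
        assert out.pixels[20, 20] == pytest.approx(1.0)

    def test_narrow_bar_on_ramp_background(self):
        # 3-px bar of amplitude 0.8 riding on a gentle ramp: the opening
        # removes the bar but follows the ramp, so the residual is the bar
        n = 80
        ramp = np.tile(np.linspace(0.0, 0.15, n), (n, 1))
        a = ramp.copy()
        a[38:41, :] += 0.8
        out = oq.top_hat(img(a), 10)
        bar_amp = out.pixels[39, 40]
        assert bar_amp == pytest.approx(0.8, abs=0.05)
        assert out.pixels[10, 40] < 0.05

    def test_radius_validation(self):
        with pytest.raises(ParameterError):
            oq.top_hat(flat_image(20), 15)
        with pytest.raises(ParameterError):
            oq.top_hat(flat_image(20), 0)


# ---------------------------------------------------------------------------
# hessian vesselness

def gaussian_ridge(n=64, sigma=2.0, axis=0, amp=1.0):
    x = np.arange(n) - n // 2
    profile = amp * np.exp(-0.5 * (x / sigma) ** 2)
    a = np.tile(profile, (n, 1))
    return a if axis == 1 else a.T


class TestHessianVesselness:
    def test_constant_image_scores_zero(self):
        out = oq.hessian_vesselness(flat_image(), 2.0)
        assert np.allclose(out.pixels, 0.0, atol=1e-12)

    def test_ridge_centreline_scores_highest(self):
        a = gaussian_ridge(sigma=2.0)
        out = oq.hessian_vesselness(img(a), 2.0)
        centre = out.pixels[32, 32]
        assert centre > out.pixels[27, 32]
        assert centre > out.pixels[37, 32]
        assert centre == pytest.approx(out.pixels.max(), rel=1e-6)

    def test_ridge_outscores_isotropic_blob(self):
        ridge = oq.hessian_vesselness(img(gaussian_ridge(sigma=2.0)), 2.0)
        x = np.arange(64) - 32
        blob = np.exp(-0.5 * (x[:, None] ** 2 + x[None, :] ** 2) / 4.0)
        blob_v = oq.hessian_vesselness(img(blob), 2.0)
        assert ridge.pixels[32, 32] >= blob_v.pixels[32, 32]

    def test_rejects_non_finite_pixels(self):
        a = np.zeros((16, 16))
        a[3, 3] = np.nan
        with pytest.raises(ValueError):
            oq.hessian_vesselness(img(a), 2.0)


# ---------------------------------------------------------------------------
# Huang threshold

from oracles import huang_cost_reference


class TestHuangThreshold:
    def test_two_level_image_split_between_modes(self):
        a = np.zeros((20, 20))
        a[:, :10], a[:, 10:] = 50 / 255, 200 / 255
        t = oq.huang_threshold(img(a))
        assert 50 / 255 < t < 200 / 255
        assert ((a > t) == (a > 100 / 255)).all()

    def test_bimodal_mixture_threshold_between_modes(self, rng):
        x = np.concatenate([rng.normal(60, 15, 20000),
                            rng.normal(180, 15, 20000)])
        t = oq.huang_threshold(np.clip(x, 0, 255) / 255)
        assert 90 / 255 <= t <= 150 / 255

    def test_single_foreground_pixel_above_threshold(self):
        a = np.zeros((32, 32))
        a[5, 7] = 1.0
        t = oq.huang_threshold(img(a))
        assert a[5, 7] > t

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateInputError):
            oq.huang_threshold(flat_image())

    def test_matches_exhaustive_reference_on_random_histograms(self, rng):
        from octaquant.binarize import _huang_argmin
        levels = np.arange(256.0)
        for _ in range(20):
            hist = rng.integers(0, 50, 256).astype(float)
            hist[rng.integers(0, 256, 200)] += rng.integers(0, 500)
            if len(np.nonzero(hist)[0]) < 2:
                continue
            ref = int(np.argmin(huang_cost_reference(hist, levels)))
            assert _huang_argmin(hist, levels) == ref

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_threshold_inside_occupied_range(self, seed):
        r = np.random.default_rng(seed)
        a = r.uniform(0.1, 0.9, (24, 24))
        t = oq.huang_threshold(img(a))
        assert a.min() <= t <= a.max()


# ---------------------------------------------------------------------------
# local median threshold

class TestLocalMedianThreshold:
    def test_constant_image_all_background(self):
        m = oq.local_median_threshold(flat_image(), 5, 0.0)
        assert not m.mask.any()

    def test_single_bright_pixel_is_foreground(self):
        a = np.zeros((40, 40))
        a[20, 20] = 1.0
        m = oq.local_median_threshold(img(a), 5, 0.0)
        assert m.mask[20, 20]
        assert m.mask.sum() == 1

    def test_narrow_bar_detected_far_field_clean(self):
        a = np.zeros((80, 80))
        a[39:41, :] = 0.8
        m = oq.local_median_threshold(img(a), 15, 0.0)
        assert m.mask[39].all() and m.mask[40].all()
        assert not m.mask[:20].any() and not m.mask[60:].any()


# ---------------------------------------------------------------------------
# mask combination and full chain

class TestCombineAndChain:
    def test_union_semantics(self, rng):
        shape = (30, 30)
        a = oq.BinaryVesselMap(rng.random(shape) < 0.2, "a")
        b = oq.BinaryVesselMap(rng.random(shape) < 0.2, "b")
        c = oq.combine_masks(a, b)
        assert c.provenance == "combined"
        assert (c.mask[a.mask]).all() and (c.mask[b.mask]).all()
        assert c.mask.sum() >= max(a.mask.sum(), b.mask.sum())

    def test_idempotent_and_identity_element(self):
        m = oq.BinaryVesselMap(np.eye(10, dtype=bool), "a")
        empty = oq.BinaryVesselMap(np.zeros((10, 10), bool), "b")
        assert (oq.combine_masks(m, m).mask == m.mask).all()
        assert (oq.combine_masks(empty, m).mask == m.mask).all()

    def test_disjoint_masks_add(self):
        a = np.zeros((40, 40), bool)
        b = np.zeros((40, 40), bool)
        a[:5, :20] = True   # 100 px
        b[20:25, :30] = True  # 150 px
        c = oq.combine_masks(oq.BinaryVesselMap(a, "a"), oq.BinaryVesselMap(b, "b"))
        assert c.mask.sum() == 250

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            oq.combine_masks(oq.BinaryVesselMap(np.zeros((5, 5), bool), "a"),
                             oq.BinaryVesselMap(np.zeros((6, 6), bool), "b"))

    def test_chain_is_deterministic(self):
        image, _ = oq.generate_phantom(oq.PhantomSpec(seed=7, grid_px=200))
        m1 = oq.binarize_scp(image)
        m2 = oq.binarize_scp(image)
        assert (m1.mask == m2.mask).all()

    def test_pure_noise_binarizes_to_nearly_nothing(self):
        fills = []
        for seed in (1, 2, 3):
            image, _ = oq.generate_phantom(oq.PhantomSpec(n_vessels=0, seed=seed))
            fills.append(oq.binarize_scp(image).fill_fraction)
        assert np.mean(fills) < 0.05
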