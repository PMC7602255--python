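"""Segmentation: Otsu thresholding, mask combination, the morphological
cascade, contour tracing and the full pipeline stage."""

import numpy as np
import pytest
from scipy import ndimage
from skimage import filters as skfilters
from skimage import draw, morphology

from melagabor.preprocess import DermoscopyImage
from melagabor import segmentation as seg
from melagabor.segmentation import (Contour, DegenerateHistogramError,
                                    EmptySegmentationError, LesionMask,
                                    area_opening, combine_masks,
                                    dice_coefficient, largest_component,
                                    median_cascade, open_close_adaptive,
                                    otsu_threshold, plane_masks, segment,
                                    size_filter, trace_contours)


def brute_force_otsu(hist):
    """Exhaustive between-class-variance search, smallest-t tie-break."""
    hist = np.asarray(hist, float)
    total = hist.sum()
    best_t, best_v = None, -1.0
    for t in range(256):
        w0 = hist[:t + 1].sum() / total
        w1 = 1.0 - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:t + 1] * np.arange(t + 1)).sum() / (w0 * total)
        mu1 = (hist[t + 1:] * np.arange(t + 1, 256)).sum() / (w1 * total)
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v + 1e-12:
            best_v, best_t = v, t
    return best_t


def disc_image(value_in=40, value_out=200, radius=60, size=256):
    pixels = np.full((size, size, 3), value_out, dtype=np.uint8)
    rr, cc = draw.disk((size // 2, size // 2), radius)
    pixels[rr, cc] = value_in
    return DermoscopyImage(pixels=pixels)


class TestOtsu:
    def test_two_adjacent_spikes(self):
        hist = np.zeros(256)
        hist[0] = 4
        hist[3] = 4
        assert otsu_threshold(hist) == 0

    def test_two_spikes_between_modes(self):
        hist = np.zeros(256)
        hist[50] = 10
        hist[200] = 10
        t = otsu_threshold(hist)
        assert 50 <= t <= 199
        assert t == brute_force_otsu(hist)

    def test_degenerate_single_level(self):
        hist = np.zeros(256)
        hist[77] = 100
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(hist)

    def test_agrees_with_skimage_on_bimodal_image(self, rng):
        img = np.concatenate([rng.normal(60, 10, 2000),
                              rng.normal(190, 10, 2000)])
        img = np.clip(img, 0, 255).astype(np.uint8)
        hist = np.bincount(img, minlength=256)
        t = otsu_threshold(hist)
        t_sk = skfilters.threshold_otsu(hist=(hist, np.arange(256)))
        assert abs(int(t) - int(t_sk)) <= 1


class TestPlaneMasks:
    def test_dark_disc_all_planes(self):
        img = disc_image()
        truth = img.pixels[:, :, 0] == 40
        for m in plane_masks(img):
            np.testing.assert_array_equal(m, truth)

    def test_constant_image_degenerate(self, caplog):
        img = DermoscopyImage(np.full((64, 64, 3), 120, np.uint8))
        with caplog.at_level("WARNING"):
            masks = plane_masks(img)
        assert all(not m.any() for m in masks)
        assert len(caplog.records) == 3

    def test_disc_dark_only_in_red(self, rng):
        pixels = np.full((128, 128, 3), 200, dtype=np.uint8)
        rr, cc = draw.disk((64, 64), 30)
        pixels[rr, cc, 0] = 40
        # G and B planes get mild noise so their own Otsu level applies
        noise = rng.integers(190, 210, (128, 128), dtype=np.uint8)
        pixels[:, :, 1] = noise
        pixels[:, :, 2] = noise
        img = DermoscopyImage(pixels)
        m_r, m_g, m_b = plane_masks(img)
        np.testing.assert_array_equal(m_r, pixels[:, :, 0] == 40)
        t_g = brute_force_otsu(np.bincount(pixels[:, :, 1].ravel(),
                                           minlength=256))
        np.testing.assert_array_equal(m_g, pixels[:, :, 1] <= t_g)


class TestCombineMasks:
    def test_unanimity(self, rng):
        m = rng.random((16, 16)) > 0.5
        np.testing.assert_array_equal(combine_masks(m, m, m).mask, m)

    def test_two_of_three(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        c = np.zeros((4, 4), bool)
        a[1, 1] = b[1, 1] = True
        assert combine_masks(a, b, c).mask[1, 1]
        a2 = np.zeros((4, 4), bool)
        a2[2, 2] = True
        assert not combine_masks(a2, b, c).mask[2, 2]

    def test_matches_per_pixel_vote_oracle(self, rng):
        masks = [rng.random((8, 8)) > 0.5 for _ in range(3)]
        out = combine_masks(*masks).mask
        for r in range(8):
            for c in range(8):
                votes = sum(int(m[r, c]) for m in masks)
                assert out[r, c] == (votes >= 2)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            combine_masks(np.zeros((4, 4), bool), np.zeros((4, 4), bool),
                          np.zeros((5, 4), bool))

    def test_and_or_rules(self, rng):
        masks = [rng.random((8, 8)) > 0.5 for _ in range(3)]
        np.testing.assert_array_equal(
            combine_masks(*masks, rule="and").mask,
            masks[0] & masks[1] & masks[2])
        np.testing.assert_array_equal(
            combine_masks(*masks, rule="or").mask,
            masks[0] | masks[1] | masks[2])


class TestAreaOpening:
    def test_empty_mask(self):
        out = area_opening(LesionMask(np.zeros((32, 32), bool)), 10)
        assert out.area == 0

    def test_removes_only_small_components(self):
        mask = np.zeros((64, 64), bool)
        mask[2:7, 2:12] = True       # area 50
        mask[20:45, 20:40] = True    # area 500
        out = area_opening(LesionMask(mask), min_area=100)
        assert out.n_components == 1
        assert out.component_areas == [500]
        np.testing.assert_array_equal(out.mask[20:45, 20:40], True)

    def test_component_exactly_at_threshold_kept(self):
        mask = np.zeros((32, 32), bool)
        mask[0:10, 0:10] = True  # area 100
        out = area_opening(LesionMask(mask), min_area=100)
        assert out.area == 100

    def test_never_adds_pixels(self, rng):
        mask = rng.random((64, 64)) > 0.6
        out = area_opening(LesionMask(mask), 20)
        assert not (out.mask & ~mask).any()


def brute_force_median(mask, size):
    """Window-vote oracle with reflective borders."""
    pad = size // 2
    # half-sample symmetric reflection, the scipy.ndimage "reflect" rule
    padded = np.pad(mask.astype(int), pad, mode="symmetric")
    out = np.zeros_like(mask, dtype=bool)
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            window = padded[r:r + size, c:c + size]
            out[r, c] = window.sum() * 2 > size * size
    return out


class TestMedianCascade:
    def test_large_rectangle_roughly_preserved(self):
        mask = np.zeros((64, 64), bool)
        mask[10:50, 10:50] = True
        out = median_cascade(LesionMask(mask))
        changed = np.argwhere(out.mask ^ mask)
        corners = np.array([[10, 10], [10, 49], [49, 10], [49, 49]])
        for r, c in changed:  # every change is corner rounding, <= 3 px deep
            assert np.abs(corners - [r, c]).max(axis=1).min() <= 3

    def test_isolated_pixel_removed(self):
        mask = np.zeros((32, 32), bool)
        mask[16, 16] = True
        assert median_cascade(LesionMask(mask)).area == 0

    def test_checkerboard_matches_sequential_oracle(self):
        mask = np.indices((16, 16)).sum(axis=0) % 2 == 0
        expected = mask
        for size in (7, 5, 3):
            expected = brute_force_median(expected, size)
        np.testing.assert_array_equal(median_cascade(LesionMask(mask)).mask,
                                      expected)


class TestOpenCloseAdaptive:
    def test_large_disc_nearly_preserved(self):
        mask = np.zeros((128, 128), bool)
        rr, cc = draw.disk((64, 64), 50)
        mask[rr, cc] = True
        out = open_close_adaptive(LesionMask(mask), radius=2)
        assert abs(out.area - mask.sum()) / mask.sum() < 0.01

    def test_isolated_pixel_removed(self):
        mask = np.zeros((64, 64), bool)
        mask[10, 10] = True
        assert open_close_adaptive(LesionMask(mask)).area == 0

    def test_spur_removed_core_matches_minkowski_oracle(self):
        mask = np.zeros((32, 32), bool)
        mask[8:24, 8:24] = True
        mask[15, 24:31] = True  # 1-px spur
        selem = morphology.disk(2)
        expected = mask
        for _ in range(2):
            expected = ndimage.binary_dilation(
                ndimage.binary_erosion(expected, selem), selem)
            expected = ndimage.binary_erosion(
                ndimage.binary_dilation(expected, selem), selem)
        out = open_close_adaptive(LesionMask(mask), radius=2)
        assert not out.mask[15, 26:31].any()
        np.testing.assert_array_equal(out.mask, expected)

    def test_default_radius_scales_with_image(self):
        assert seg.adaptive_element_radius((256, 256)) == 3
        assert seg.adaptive_element_radius((64, 64)) == 1


class TestSizeFilter:
    def test_arithmetic_cutoff(self):
        mask = np.zeros((256, 256), bool)
        mask[0:40, 0:50] = True       # 2000 px < 3276.8
        mask[100:150, 100:200] = True  # 5000 px
        out = size_filter(LesionMask(mask))
        assert out.component_areas == [5000]

    def test_large_component_unchanged(self):
        mask = np.zeros((64, 64), bool)
        mask[4:60, 4:48] = True  # ~60% of the frame
        out = size_filter(LesionMask(mask))
        np.testing.assert_array_equal(out.mask, mask)

    def test_empty_signal_and_fallback(self):
        mask = np.zeros((256, 256), bool)
        mask[0:10, 0:10] = True
        mask[50:70, 50:70] = True
        lm = LesionMask(mask)
        with pytest.raises(EmptySegmentationError):
            size_filter(lm)
        kept = largest_component(lm)
        assert kept.component_areas == [400]

    def test_never_adds_pixels(self, rng):
        mask = rng.random((64, 64)) > 0.4
        lm = LesionMask(mask)
        try:
            out = size_filter(lm)
        except EmptySegmentationError:
            out = largest_component(lm)
        assert not (out.mask & ~mask).any()


class TestTraceContours:
    def test_empty_mask(self):
        assert trace_contours(LesionMask(np.zeros((16, 16), bool))) == []

    def test_disc_contour_length(self):
        mask = np.zeros((128, 128), bool)
        rr, cc = draw.disk((64, 64), 40)
        mask[rr, cc] = True
        (contour,) = trace_contours(LesionMask(mask))
        assert contour.closed
        perimeter = 2 * np.pi * 40
        assert abs(len(contour.points) - perimeter) / perimeter < 0.15

    def test_rectangle_bounding_box(self):
        mask = np.zeros((64, 64), bool)
        mask[10:30, 20:50] = True  # 20 x 30 rectangle
        (contour,) = trace_contours(LesionMask(mask))
        pts = contour.points
        assert pts[:, 0].min() == 10 and pts[:, 0].max() == 29
        assert pts[:, 1].min() == 20 and pts[:, 1].max() == 49

    def test_chain_is_8_connected_and_closed(self, rng):
        mask = np.zeros((64, 64), bool)
        rr, cc = draw.ellipse(32, 32, 15, 22)
        mask[rr, cc] = True
        (contour,) = trace_contours(LesionMask(mask))
        pts = contour.points
        steps = np.abs(np.diff(pts, axis=0))
        assert (steps.max(axis=1) == 1).all()
        closing_step = np.abs(pts[0] - pts[-1])
        assert closing_step.max() <= 1

    def test_single_pixel_component(self):
        mask = np.zeros((8, 8), bool)
        mask[3, 3] = True
        (contour,) = trace_contours(LesionMask(mask))
        np.testing.assert_array_equal(contour.points, [[3, 3]])


class TestSegment:
    def test_clean_disc(self):
        img = disc_image(radius=70)
        mask, contours = segment(img)
        truth = img.pixels[:, :, 0] == 40
        assert dice_coefficient(mask.mask, truth) > 0.98
        assert len(contours) == 1

    def test_synthetic_blob_dice(self, default_cohort):
        from melagabor import pipeline
        _, samples = default_cohort
        sample = samples[0]
        mask, _, _ = pipeline.segment_image(sample.image,
                                            pipeline.PipelineConfig())
        assert dice_coefficient(mask.mask, sample.truth_mask.mask) >= 0.85

    def test_constant_image_empty_with_warning(self, caplog):
        img = DermoscopyImage(np.full((256, 256, 3), 150, np.uint8))
        with caplog.at_level("WARNING"):
            mask, contours = segment(img)
        assert mask.area == 0 and contours == []
        assert any("empty segmentation" in r.message for r in caplog.records)

    def test_small_second_blob_removed(self):
        pixels = np.full((256, 256, 3), 200, dtype=np.uint8)
        rr, cc = draw.disk((100, 100), 80)   # ~30% of frame
        pixels[rr, cc] = 40
        rr, cc = draw.disk((220, 220), 20)   # ~2% of frame
        pixels[rr, cc] = 40
        mask, _ = segment(DermoscopyImage(pixels))
        assert mask.n_components == 1
        assert not mask.mask[220, 220]
        assert mask.mask[100, 100]

    def test_mask_within_dilated_plane_union(self, rng):
        pixels = np.full((128, 128, 3), 190, dtype=np.uint8)
        rr, cc = draw.disk((64, 64), 35)
        pixels[rr, cc] = 60
        pixels = np.clip(pixels.astype(int)
                         + rng.normal(0, 8, pixels.shape), 0, 255
                         ).astype(np.uint8)
        img = DermoscopyImage(pixels)
        m1, m2, m3 = plane_masks(img)
        mask, _ = segment(img)
        union = m1 | m2 | m3
        radius = seg.adaptive_element_radius(pixels.shape)
        allowed = ndimage.binary_dilation(union, morphology.disk(radius),
                                          iterations=2)
        assert not (mask.mask & ~allowed).any()
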