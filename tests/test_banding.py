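"""Threshold banding, hotmap composition and expression-domain measurement."""

import numpy as np
import pytest

from toothmap import (
    GrayImage8,
    ROIMask,
    ThresholdSet,
    band_images,
    compose_hotmap,
    domain_size,
    sample_unit_bands,
    threshold_image,
)
from toothmap.banding import DEFAULT_LEVELS

from conftest import random_image


def brute_force_band(pixels, low, high):
    """Independent oracle: the half-open interval mask by explicit loop."""
    out = np.zeros_like(pixels, dtype=bool)
    for r in range(pixels.shape[0]):
        for c in range(pixels.shape[1]):
            out[r, c] = low <= pixels[r, c] < high
    return out


def constant(value, shape=(32, 32)):
    return GrayImage8(np.full(shape, value, dtype=np.uint8))


class TestThresholdImage:
    def test_inclusive_at_threshold(self):
        assert threshold_image(constant(15), 15).all()

    def test_below_threshold_empty(self):
        assert not threshold_image(constant(14), 15).any()

    def test_matches_brute_force_count(self, rng):
        img = random_image(rng)
        assert threshold_image(img, 95).sum() == int((img.pixels >= 95).sum())

    @pytest.mark.parametrize("t", [0, 256])
    def test_rejects_out_of_range(self, t):
        with pytest.raises(ValueError):
            threshold_image(constant(0), t)


class TestBandImages:
    def test_default_levels_emit_six_subtraction_products_plus_top(self, rng):
        bands = band_images(random_image(rng))
        assert len([b for b in bands if b.subtraction_product]) == 6
        assert len(bands) == 7
        assert bands[-1].interval == (95, 256)
        assert bands[-1].color_label == "yellow"
        assert not bands[-1].subtraction_product

    def test_band_colors_in_order(self, rng):
        labels = [b.color_label for b in band_images(random_image(rng))]
        assert labels == [
            "dark blue", "bright blue", "dark green", "bright green",
            "dark red", "bright red", "yellow",
        ]

    def test_constant_50_fills_only_dark_green(self):
        bands = band_images(constant(50))
        for b in bands:
            if b.interval == (45, 55):
                assert b.mask.all()
            else:
                assert not b.mask.any()

    def test_equals_brute_force_interval_masks(self, rng):
        """The colorize-merge-subtract route equals direct interval banding."""
        for _ in range(20):
            img = random_image(rng, (16, 16))
            for band in band_images(img):
                np.testing.assert_array_equal(
                    band.mask, brute_force_band(img.pixels, *band.interval)
                )

    def test_partition_of_baseline_mask(self, rng):
        img = random_image(rng)
        bands = band_images(img)
        union = np.zeros(img.shape, dtype=int)
        for b in bands:
            union += b.mask.astype(int)
        assert union.max() <= 1
        np.testing.assert_array_equal(union.astype(bool), threshold_image(img, 15))

    def test_custom_threshold_set(self, rng):
        ts = ThresholdSet((10, 100, 200))
        bands = band_images(random_image(rng), ts)
        assert [b.interval for b in bands] == [(10, 100), (100, 200), (200, 256)]


class TestThresholdSet:
    def test_default_levels(self):
        assert ThresholdSet().levels == (15, 30, 45, 55, 70, 85, 95)
        assert ThresholdSet().baseline == 15

    @pytest.mark.parametrize("levels", [(15,), (15, 15), (30, 15), (0, 15), (15, 256)])
    def test_invalid_levels_rejected(self, levels):
        with pytest.raises(ValueError):
            ThresholdSet(levels)


class TestHotmap:
    def test_full_partition_labels_every_above_baseline_pixel(self, rng):
        img = random_image(rng)
        hot = compose_hotmap(band_images(img))
        above = threshold_image(img, 15)
        np.testing.assert_array_equal(hot.labels >= 0, above)

    def test_empty_bands_give_empty_hotmap(self):
        hot = compose_hotmap(band_images(constant(0)))
        assert (hot.labels == -1).all()

    def test_overlapping_bands_rejected(self, rng):
        img = random_image(rng)
        bands = band_images(img)
        with pytest.raises(ValueError, match="overlap"):
            compose_hotmap(list(bands) + [bands[0]])

    def test_label_counts_match_domain_band_histogram(self, default_phantom):
        img = default_phantom.channels["green"]
        hot = compose_hotmap(band_images(img))
        roi = ROIMask(np.ones(img.shape, dtype=bool), "whole_frame")
        hist = domain_size(img, roi).band_histogram
        assert hot.label_counts() == hist

    def test_rgb_render_uses_palette(self, rng):
        hot = compose_hotmap(band_images(constant(50)))
        rgb = hot.to_rgb()
        assert tuple(rgb[0, 0]) == (0, 100, 0)  # dark green


class TestDomainSize:
    def test_blank_image_zero_fraction(self):
        roi = ROIMask(np.ones((32, 32), dtype=bool))
        assert domain_size(constant(0), roi).fraction == 0.0

    def test_saturated_image_full_fraction(self):
        roi = ROIMask(np.ones((32, 32), dtype=bool))
        m = domain_size(constant(255), roi)
        assert m.fraction == 100.0
        assert m.domain_area == m.roi_area == 32 * 32

    def test_band_histogram_sums_to_domain_area(self, rng):
        img = random_image(rng)
        roi = ROIMask(img.pixels % 2 == 0, "even")
        m = domain_size(img, roi)
        assert sum(m.band_histogram.values()) == m.domain_area

    def test_fraction_non_increasing_in_baseline(self, rng):
        img = random_image(rng)
        roi = ROIMask(np.ones(img.shape, dtype=bool))
        fractions = [
            domain_size(img, roi, ThresholdSet((t, 255))).fraction
            for t in (5, 15, 40, 90, 150)
        ]
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))

    def test_noiseless_phantom_recovers_ground_truth(self, clean_phantom):
        roi = ROIMask(np.ones(clean_phantom.channels["green"].shape, dtype=bool), "whole_frame")
        for ch in ("green", "red"):
            measured = domain_size(clean_phantom.channels[ch], roi).fraction
            truth = clean_phantom.true_domain_fraction[(ch, "whole_frame")]
            assert measured == pytest.approx(truth, abs=0.5)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ROIMask(np.zeros((8, 8), dtype=bool))

    def test_shape_mismatch_rejected(self):
        roi = ROIMask(np.ones((8, 8), dtype=bool))
        with pytest.raises(ValueError, match="does not match"):
            domain_size(constant(0, (9, 9)), roi)


class TestSampleUnitBands:
    def test_default_emits_sixteen_five_pixel_bands(self, rng):
        bands = sample_unit_bands(random_image(rng))
        assert len(bands) == (95 - 15) // 5 == 16
        assert bands[0].interval == (15, 20)
        assert bands[-1].interval == (90, 95)

    def test_single_band_when_step_spans_range(self, rng):
        bands = sample_unit_bands(random_image(rng), low=15, high=30, step=15)
        assert [b.interval for b in bands] == [(15, 30)]

    def test_union_covers_exactly_the_range(self, rng):
        img = random_image(rng)
        union = np.zeros(img.shape, dtype=int)
        for b in sample_unit_bands(img):
            union += b.mask.astype(int)
        assert union.max() <= 1
        np.testing.assert_array_equal(
            union.astype(bool), (img.pixels >= 15) & (img.pixels < 95)
        )

    def test_non_dividing_step_rejected(self, rng):
        with pytest.raises(ValueError, match="divide"):
            sample_unit_bands(random_image(rng), low=15, high=95, step=7)

    def test_inverted_range_rejected(self, rng):
        with pytest.raises(ValueError, match="less than"):
            sample_unit_bands(random_image(rng), low=95, high=15, step=5)
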