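"""Color conversions, channel stacking and the 72-variable summary.

The conversion oracles here are written independently of the package:
scalar, step-by-step evaluations of the published hexcone, BT.601 and
sRGB→XYZ→Lab formulas.
"""

import colorsys

import numpy as np
import pandas as pd
import pytest
from skimage import color as skcolor

from stripscreen import (
    CHANNELS,
    FEATURE_SCHEMA,
    SUMMARIES,
    StripImage,
    combined_rgb_value,
    extract_channels,
    extract_features,
    extract_features_batch,
    rgb_to_cielab,
    rgb_to_hsv,
    rgb_to_ycbcr,
    summarize_channels,
)

# ---------------------------------------------------------------- oracles


def oracle_hsv(r, g, b):
    h, s, v = colorsys.rgb_to_hsv(r / 255.0, g / 255.0, b / 255.0)
    return h * 360.0, s, v


def oracle_ycbcr(r, g, b):
    y = 0.299 * r + 0.587 * g + 0.114 * b
    cb = 128.0 - 0.168735892 * r - 0.331264108 * g + 0.5 * b
    cr = 128.0 + 0.5 * r - 0.418687589 * g - 0.081312411 * b
    return tuple(min(255.0, max(0.0, c)) for c in (y, cb, cr))


def oracle_lab(r, g, b):
    def invgamma(u):
        u = u / 255.0
        return u / 12.92 if u <= 0.04045 else ((u + 0.055) / 1.055) ** 2.4

    rl, gl, bl = invgamma(r), invgamma(g), invgamma(b)
    x = 0.4124564 * rl + 0.3575761 * gl + 0.1804375 * bl
    y = 0.2126729 * rl + 0.7151522 * gl + 0.0721750 * bl
    z = 0.0193339 * rl + 0.1191920 * gl + 0.9503041 * bl
    # white point = matrix row sums (D65)
    xn = 0.4124564 + 0.3575761 + 0.1804375
    yn = 0.2126729 + 0.7151522 + 0.0721750
    zn = 0.0193339 + 0.1191920 + 0.9503041

    def f(t):
        d = 6.0 / 29.0
        return t ** (1.0 / 3.0) if t > d**3 else t / (3 * d * d) + 4.0 / 29.0

    fx, fy, fz = f(x / xn), f(y / yn), f(z / zn)
    return 116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)


# ------------------------------------------------------------ conversions


class TestConversions:
    def test_primary_red_hsv(self):
        h, s, v = rgb_to_hsv(np.array([255.0, 0.0, 0.0]))
        assert (h, s, v) == (0.0, 1.0, 1.0)

    def test_achromatic_hsv(self):
        h, s, v = rgb_to_hsv(np.array([128.0, 128.0, 128.0]))
        assert h == 0.0 and s == 0.0 and v == pytest.approx(128 / 255)

    def test_gray_and_white_ycbcr(self):
        assert rgb_to_ycbcr(np.array([128.0, 128.0, 128.0])) == pytest.approx(
            (128.0, 128.0, 128.0), abs=1e-9
        )
        y, cb, cr = rgb_to_ycbcr(np.array([255.0, 255.0, 255.0]))
        assert y == pytest.approx(255.0) and cb == pytest.approx(128.0) and cr == pytest.approx(128.0)

    def test_lab_white_and_black(self):
        L, a, b = rgb_to_cielab(np.array([255.0, 255.0, 255.0]))
        assert L == pytest.approx(100.0, abs=1e-4)
        assert abs(a) < 0.01 and abs(b) < 0.01
        L, a, b = rgb_to_cielab(np.array([0.0, 0.0, 0.0]))
        assert (L, a, b) == (0.0, 0.0, 0.0)

    def test_purple_pixel_matches_oracles(self):
        px = np.array([120.0, 40.0, 160.0])
        assert rgb_to_hsv(px) == pytest.approx(oracle_hsv(*px), abs=1e-9)
        assert rgb_to_ycbcr(px) == pytest.approx(oracle_ycbcr(*px), abs=1e-9)
        assert rgb_to_cielab(px) == pytest.approx(oracle_lab(*px), abs=1e-9)

    def test_random_pixels_match_oracles(self, rng):
        pixels = rng.integers(0, 256, size=(1000, 3)).astype(float)
        h, s, v = rgb_to_hsv(pixels)
        y, cb, cr = rgb_to_ycbcr(pixels)
        L, a, b = rgb_to_cielab(pixels)
        for i, (r_, g_, b_) in enumerate(pixels):
            oh, os_, ov = oracle_hsv(r_, g_, b_)
            assert (h[i], s[i], v[i]) == pytest.approx((oh, os_, ov), abs=1e-6)
            assert (y[i], cb[i], cr[i]) == pytest.approx(oracle_ycbcr(r_, g_, b_), abs=1e-6)
            assert (L[i], a[i], b[i]) == pytest.approx(oracle_lab(r_, g_, b_), abs=1e-6)

    def test_lab_cross_check_against_skimage(self, rng):
        # independent library route; skimage uses a higher-precision sRGB
        # matrix, so agreement is at the 1e-2 level, not machine precision
        pixels = rng.integers(0, 256, size=(200, 3)).astype(float)
        L, a, b = rgb_to_cielab(pixels)
        ref = skcolor.rgb2lab(pixels[None, :, :] / 255.0)[0]
        assert np.abs(np.stack([L, a, b], axis=1) - ref).max() < 0.01

    def test_out_of_range_rejected(self):
        for bad in ([300.0, 0.0, 0.0], [-1.0, 0.0, 0.0], [np.nan, 0.0, 0.0]):
            with pytest.raises(ValueError):
                rgb_to_hsv(np.array(bad))
            with pytest.raises(ValueError):
                rgb_to_ycbcr(np.array(bad))
            with pytest.raises(ValueError):
                rgb_to_cielab(np.array(bad))


# --------------------------------------------------------- channel stack


class TestChannelStack:
    def test_stack_has_twelve_channels(self, rng):
        img = rng.integers(0, 256, size=(5, 7, 3)).astype(np.uint8)
        stack = extract_channels(img)
        assert stack.data.shape == (5, 7, 12)
        assert stack.channels == CHANNELS

    def test_white_image_stack(self):
        stack = extract_channels(np.full((1, 1, 3), 255, dtype=np.uint8))
        vals = dict(zip(CHANNELS, stack.data[0, 0]))
        assert vals["R"] == vals["G"] == vals["B"] == 255
        assert vals["H"] == 0.0 and vals["S"] == 0.0 and vals["V"] == 1.0
        assert vals["Y"] == pytest.approx(255.0)
        assert vals["Cb"] == pytest.approx(128.0) and vals["Cr"] == pytest.approx(128.0)
        assert vals["Lstar"] == pytest.approx(100.0, abs=1e-4)
        assert abs(vals["astar"]) < 0.01 and abs(vals["bstar"]) < 0.01
        assert stack.hue_degenerate[0, 0]

    def test_stack_equals_per_pixel_scalar_conversion(self, rng):
        img = rng.integers(0, 256, size=(2, 2, 3)).astype(np.uint8)
        stack = extract_channels(img)
        for i in range(2):
            for j in range(2):
                r_, g_, b_ = img[i, j].astype(float)
                expected = [r_, g_, b_, *oracle_hsv(r_, g_, b_),
                            *oracle_ycbcr(r_, g_, b_), *oracle_lab(r_, g_, b_)]
                assert stack.data[i, j] == pytest.approx(expected, abs=1e-9)

    def test_gray_line_property(self, rng):
        grays = np.repeat(rng.integers(0, 256, size=(20, 1)), 3, axis=1).astype(float)
        stack = extract_channels(grays[None, :, :])
        assert np.all(stack.channel("S") == 0)
        assert np.allclose(stack.channel("Cb"), 128.0)
        assert np.allclose(stack.channel("Cr"), 128.0)
        assert np.abs(stack.channel("astar")).max() < 0.01
        assert np.abs(stack.channel("bstar")).max() < 0.01
        assert stack.hue_degenerate.all()


# -------------------------------------------------------------- summaries


class TestSummaries:
    def test_schema_is_72_names(self):
        assert len(FEATURE_SCHEMA) == 72
        assert len(set(FEATURE_SCHEMA)) == 72
        assert FEATURE_SCHEMA == tuple(f"{c}_{s}" for c in CHANNELS for s in SUMMARIES)

    def test_feature_vector_has_72_entries(self, rng):
        img = rng.integers(0, 256, size=(4, 4, 3)).astype(np.uint8)
        feats = summarize_channels(extract_channels(img))
        assert list(feats.index) == list(FEATURE_SCHEMA)
        assert len(feats) == 72

    def test_constant_image_degenerate_summaries(self):
        img = np.full((3, 3, 3), 90, dtype=np.uint8)
        feats = summarize_channels(extract_channels(img))
        for ch in CHANNELS:
            assert feats[f"{ch}_min"] == feats[f"{ch}_max"] == feats[f"{ch}_mean"] == feats[f"{ch}_median"]
            assert feats[f"{ch}_sd"] == 0.0
            assert feats[f"{ch}_range"] == 0.0

    def test_hand_computed_red_channel_summaries(self):
        # 2x2 image whose R channel is {10, 20, 30, 100}; G=B=0
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        img[..., 0] = [[10, 20], [30, 100]]
        feats = summarize_channels(extract_channels(img))
        assert feats["R_min"] == 10 and feats["R_max"] == 100
        assert feats["R_mean"] == 40 and feats["R_median"] == 25
        assert feats["R_range"] == 90
        assert feats["R_sd"] == pytest.approx(np.sqrt(5000.0 / 3.0))

    def test_summary_invariants_on_random_images(self, rng):
        img = rng.integers(0, 256, size=(6, 5, 3)).astype(np.uint8)
        feats = summarize_channels(extract_channels(img))
        for ch in CHANNELS:
            assert feats[f"{ch}_range"] == feats[f"{ch}_max"] - feats[f"{ch}_min"]
            assert feats[f"{ch}_sd"] >= 0
            assert feats[f"{ch}_min"] <= feats[f"{ch}_median"] <= feats[f"{ch}_max"]

    def test_single_pixel_sd_is_zero(self):
        feats = summarize_channels(extract_channels(np.full((1, 1, 3), 7, dtype=np.uint8)))
        assert all(feats[f"{ch}_sd"] == 0.0 for ch in CHANNELS)


# --------------------------------------------------- combined RGB / misc


class TestCombinedRGB:
    def test_uniform_image(self):
        assert combined_rgb_value(np.full((4, 4, 3), 90, dtype=np.uint8)) == 90.0

    def test_black_pixel_floor(self):
        img = np.full((2, 2, 3), 200, dtype=np.uint8)
        img[1, 1] = 0
        assert combined_rgb_value(img) == 0.0

    def test_enumerated_pixel_means(self):
        # per-pixel means 120.0, 260/3, 421/3, 101.0 -> min = 260/3
        img = np.array(
            [[[120, 120, 120], [100, 80, 80]], [[200, 150, 71], [101, 101, 101]]],
            dtype=np.uint8,
        )
        means = img.astype(float).mean(axis=-1)
        assert combined_rgb_value(img) == pytest.approx(means.min())
        assert combined_rgb_value(img) == pytest.approx(260.0 / 3.0)

    def test_darkening_monotonicity(self, rng):
        img = rng.integers(30, 226, size=(5, 5, 3)).astype(float)
        dark = np.floor(img * 0.7)
        f_orig = summarize_channels(extract_channels(img.astype(np.uint8)))
        f_dark = summarize_channels(extract_channels(dark.astype(np.uint8)))
        for ch in ("V", "Y", "Lstar"):
            assert f_dark[f"{ch}_mean"] <= f_orig[f"{ch}_mean"]
        assert combined_rgb_value(dark.astype(np.uint8)) <= combined_rgb_value(img.astype(np.uint8))

    def test_batch_matches_per_image_extraction(self, rng):
        imgs = rng.integers(0, 256, size=(6, 4, 4, 3)).astype(np.uint8)
        batch = extract_features_batch(imgs, [f"p{i}" for i in range(6)], range(20, 26))
        for i in range(6):
            single = extract_features(imgs[i])
            row = batch.iloc[i]
            for name in FEATURE_SCHEMA:
                assert row[name] == pytest.approx(single[name], abs=1e-9)
            assert row["combined_rgb_min"] == pytest.approx(single["combined_rgb_min"])

    def test_strip_image_validates(self):
        with pytest.raises(ValueError):
            StripImage(pixels=np.zeros((0, 3, 3)))
        with pytest.raises(ValueError):
            StripImage(pixels=np.zeros((3, 3)))
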