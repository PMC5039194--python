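import numpy as np
import pandas as pd
import pytest

from phenorosette.color import (
    build_hue_palette,
    collect_calibration_pixels,
    hue_abundance,
    hue_salt_ratio,
    segment_colors,
)

NINE = np.array(
    [(20, 70, 25), (30, 90, 30), (42, 105, 36), (54, 120, 42), (66, 135, 50),
     (80, 150, 60), (96, 165, 72), (116, 180, 88), (140, 196, 108)], float
)


def pixel_frame(colors, reps):
    arr = np.repeat(np.asarray(colors, float), reps, axis=0)
    return pd.DataFrame(arr, columns=["R", "G", "B"])


def img_mask(colors_flat, w=10):
    colors_flat = np.asarray(colors_flat)
    h = len(colors_flat) // w
    img = colors_flat[: h * w].reshape(h, w, 3).astype(np.uint8)
    return img, np.ones((h, w), bool)


def test_collect_pixels_counts_and_cap():
    img1, m1 = img_mask(np.tile(NINE[0], (100, 1)))
    img2, m2 = img_mask(np.tile(NINE[1], (200, 1)))
    px = collect_calibration_pixels([(img1, m1), (img2, m2)])
    assert len(px) == 300
    capped = collect_calibration_pixels([(img1, m1), (img2, m2)], cap_per_image=50, seed=0)
    assert len(capped) == 100
    again = collect_calibration_pixels([(img1, m1), (img2, m2)], cap_per_image=50, seed=0)
    assert capped.equals(again)


def test_background_only_image_contributes_nothing():
    img, m = img_mask(np.tile(NINE[0], (50, 1)))
    empty = np.zeros_like(m)
    px = collect_calibration_pixels([(img, m), (img, empty)])
    assert len(px) == 50
    with pytest.raises(ValueError, match="no rosette pixels"):
        collect_calibration_pixels([(img, empty)])


def test_kmeans_recovers_nine_exact_colors():
    px = pixel_frame(NINE, 12)
    pal = build_hue_palette(px, k=9, seed=0)
    assert pal.wcss == pytest.approx(0.0, abs=1e-9)
    # luminance-sorted centroids equal the generating colours
    np.testing.assert_allclose(pal.centroids, NINE, atol=1e-9)


def test_k1_centroid_is_dataset_mean():
    px = pixel_frame(NINE, 3)
    pal = build_hue_palette(px, k=1, seed=0)
    np.testing.assert_allclose(pal.centroids[0], NINE.mean(axis=0), atol=1e-9)


def test_too_few_distinct_colors_raises_with_counts():
    px = pixel_frame(NINE[:8], 10)
    with pytest.raises(ValueError, match="k=9.*8"):
        build_hue_palette(px, k=9)


def test_palette_deterministic_under_seed():
    rng = np.random.default_rng(1)
    px = pd.DataFrame(rng.uniform(0, 255, (500, 3)), columns=["R", "G", "B"])
    a = build_hue_palette(px, k=9, seed=5)
    b = build_hue_palette(px, k=9, seed=5)
    np.testing.assert_array_equal(a.centroids, b.centroids)


def test_segment_exact_centroid_and_tie_rule():
    pal = build_hue_palette(pixel_frame(NINE, 12), k=9, seed=0)
    img, m = img_mask(np.tile(NINE[3], (10, 1)))
    assert (segment_colors(img, m, pal)[m] == 3).all()
    # equidistant pixel between centroids 0 and 1 -> lowest index wins
    mid = (NINE[0] + NINE[1]) / 2
    img2, m2 = img_mask(np.tile(np.round(mid), (10, 1)))
    d0 = np.linalg.norm(np.round(mid) - NINE[0])
    d1 = np.linalg.norm(np.round(mid) - NINE[1])
    if d0 == d1:  # rounding kept it equidistant
        assert (segment_colors(img2, m2, pal)[m2] == 0).all()


def test_segment_alignment_checked():
    pal = build_hue_palette(pixel_frame(NINE, 12), k=9, seed=0)
    img, _ = img_mask(np.tile(NINE[0], (50, 1)))
    with pytest.raises(ValueError, match="aligned"):
        segment_colors(img, np.ones((3, 3), bool), pal)


def test_abundance_basic_and_mismatch():
    labels = np.full((2, 5), 4, np.int16)
    ab = hue_abundance(labels, 10, k=9)
    assert ab.fractions[4] == 1.0 and ab.fractions.sum() == 1.0
    labels2 = np.array([[1] * 6 + [2] * 4], np.int16)
    ab2 = hue_abundance(labels2, 10, k=9)
    assert ab2.fractions[1] == pytest.approx(0.6)
    assert ab2.fractions[2] == pytest.approx(0.4)
    with pytest.raises(ValueError, match="mismatch"):
        hue_abundance(labels, 99, k=9)


def test_zero_area_plant_flagged_missing():
    ab = hue_abundance(np.full((4, 4), -1, np.int16), 0, plant_id="p", day=1)
    assert ab.missing


def test_hue_salt_ratio_values_and_guards():
    design = pd.DataFrame(
        {"plant_id": ["p1", "p2", "p3", "p4"], "accession": ["a"] * 4,
         "treatment": ["control", "control", "salt", "salt"]}
    )
    ab = pd.DataFrame(
        {"plant_id": ["p1", "p2", "p3", "p4"], "day": 1, "hue": 1,
         "fraction": [0.1, 0.2, 0.3, 0.3]}
    )
    out = hue_salt_ratio(ab, design)
    assert out.ratio.item() == pytest.approx(0.3 / 0.15)
    ab0 = ab.assign(fraction=[0.0, 0.0, 0.3, 0.3])
    assert np.isnan(hue_salt_ratio(ab0, design).ratio.item())
    with pytest.raises(ValueError, match="missing treatment arm"):
        hue_salt_ratio(ab[ab.plant_id.isin(["p1", "p2"])], design)
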