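"""Stain classification: color-range thresholding, coherence dilation, the
training montage, and the pixel classifier against generator ground truth."""

import numpy as np
import pytest

import skinquant as sq
from skinquant.errors import StainClassificationError
from skinquant.stain import (
    apply_classifier,
    apply_mask_edits,
    compose_training_image,
    train_pixel_classifier,
)
from skinquant.synthetic import generate_training_tiles

from conftest import dab_spec

CALIB = sq.ScaleCalibration(2.2)


def uniform_image(color, shape=(8, 8)):
    return sq.CalibratedImage(
        pixels=np.tile(np.asarray(color, dtype=np.uint8), (*shape, 1)), calibration=CALIB
    )


def test_threshold_exact_color_all_true():
    img = uniform_image((120, 60, 30))
    mask = sq.threshold_classify(img, sq.ColorRangeSpec(((120, 60, 30),), tolerance=0))
    assert mask.mask.all() and mask.provenance == "threshold"


def test_threshold_other_color_all_false():
    img = uniform_image((120, 60, 30))
    mask = sq.threshold_classify(img, sq.ColorRangeSpec(((121, 60, 30),), tolerance=0))
    assert not mask.mask.any()


def test_threshold_recovers_painted_area_exactly(small_section):
    image, gt = small_section
    mask = sq.threshold_classify(image, dab_spec(gt))
    assert mask.area_px == gt.stain_mask.sum()
    assert np.array_equal(mask.mask, gt.stain_mask)


def test_threshold_monotone_in_tolerance():
    rng = np.random.default_rng(2)
    img = sq.CalibratedImage(
        pixels=rng.integers(0, 256, size=(32, 32, 3), dtype=np.uint8).astype(np.uint8),
        calibration=CALIB,
    )
    ref = ((135, 85, 45), (20, 200, 120))
    masks = [
        sq.threshold_classify(img, sq.ColorRangeSpec(ref, tolerance=t)).mask
        for t in (0, 30, 60, 120, 250)
    ]
    for small, large in zip(masks, masks[1:]):
        assert (small <= large).all()


def test_spec_validation():
    with pytest.raises(StainClassificationError):
        sq.ColorRangeSpec((), tolerance=10)
    with pytest.raises(StainClassificationError):
        sq.ColorRangeSpec(((0, 0, 300),), tolerance=10)


def test_coherence_expand_single_pixel_disk():
    m = np.zeros((11, 11), dtype=bool)
    m[5, 5] = True
    grown = sq.coherence_expand(sq.PositiveMask(m), radius_px=2)
    assert grown.mask.sum() == 13  # offsets with dr^2 + dc^2 <= 4
    assert grown.mask[5, 5]


def test_coherence_expand_extensive_and_monotone():
    rng = np.random.default_rng(5)
    m = sq.PositiveMask(rng.random((30, 30)) < 0.05)
    r1 = sq.coherence_expand(m, 1).mask
    r2 = sq.coherence_expand(m, 2).mask
    assert (m.mask <= r1).all() and (r1 <= r2).all()


def test_coherence_expand_merges_nearby_blobs():
    from skimage.measure import label

    m = np.zeros((9, 15), dtype=bool)
    m[4, 2:5] = True
    m[4, 8:11] = True  # 3 px gap
    grown = sq.coherence_expand(sq.PositiveMask(m), radius_px=2)
    assert label(grown.mask, connectivity=2).max() == 1


def test_coherence_expand_empty_stays_empty():
    m = sq.PositiveMask(np.zeros((6, 6), dtype=bool))
    assert not sq.coherence_expand(m, 2).mask.any()


def test_mask_edits_xor():
    from shapely.geometry import Polygon

    m = np.zeros((10, 10), dtype=bool)
    m[0:10, 0:5] = True
    edited = apply_mask_edits(
        sq.PositiveMask(m), [Polygon([(0, 0), (10, 0), (10, 10), (0, 10)])]
    )
    assert edited.provenance == "manual"
    assert not edited.mask[:, 0:5].any() and edited.mask[:, 5:10].all()


# --- training montage ------------------------------------------------------


def _two_color_tile(positive: bool, side_px=44, side_um=20.0):
    color = (135, 85, 45) if positive else (225, 210, 222)
    px = np.tile(np.asarray(color, dtype=np.uint8), (side_px, side_px, 1))
    labels = np.full((side_px, side_px), 1 if positive else 2, dtype=np.int8)
    return sq.TrainingTile(pixels=px, labels=labels, side_um=side_um, calibration=CALIB)


def test_montage_of_four_100um_tiles_has_110px_blocks(default_cohort):
    image, gt = default_cohort[0]
    tiles = generate_training_tiles(image, gt, n_tiles=4, tile_um=100.0, seed=3)
    composite, labels = compose_training_image(tiles, working_um_per_px=0.91)
    side = round(100 / 0.91)
    assert side == 110
    assert composite.shape == (2 * side, 2 * side, 3)
    assert labels.shape == (2 * side, 2 * side)


def test_single_tile_montage_is_the_tile():
    tile = _two_color_tile(True)
    composite, labels = compose_training_image([tile], working_um_per_px=0.91)
    side = round(tile.side_um / 0.91)
    assert composite.shape == (side, side, 3)
    assert (labels == 1).all()


def test_montage_preserves_labels_from_both_sources():
    composite, labels = compose_training_image(
        [_two_color_tile(True), _two_color_tile(False)]
    )
    assert (labels == 1).any() and (labels == 2).any()
    assert not (labels == 0).any()


def test_empty_tile_list_rejected():
    with pytest.raises(StainClassificationError):
        compose_training_image([])


# --- pixel classifier ------------------------------------------------------


@pytest.fixture(scope="module")
def separable_classifier():
    tiles = [_two_color_tile(True), _two_color_tile(False)]
    composite, labels = compose_training_image(tiles)
    return train_pixel_classifier(composite, labels, seed=4)


def test_training_accuracy_on_separable_colors(separable_classifier):
    assert separable_classifier.training_accuracy >= 0.99


def test_single_class_training_rejected():
    composite, labels = compose_training_image([_two_color_tile(True)])
    with pytest.raises(StainClassificationError, match="single-class"):
        train_pixel_classifier(composite, labels, seed=0)


def test_training_is_deterministic():
    tiles = [_two_color_tile(True), _two_color_tile(False)] * 2
    composite, labels = compose_training_image(tiles)
    img, _ = sq.generate_section(sq.SectionParams(seed=3, width_um=100,
                                                  epidermis_thickness_um=40,
                                                  band_depth_um=60, apical_offset_um=15,
                                                  undulation_amplitude_um=4,
                                                  undulation_wavelength_um=80,
                                                  bottom_margin_um=10,
                                                  n_epidermal_cells=3, n_dermal_cells=5))
    masks = []
    for _ in range(2):
        clf = train_pixel_classifier(composite, labels, seed=9)
        masks.append(apply_classifier(img, clf).mask)
    assert np.array_equal(masks[0], masks[1])


def test_apply_on_uniform_training_colors(separable_classifier):
    assert apply_classifier(uniform_image((135, 85, 45), (24, 24)), separable_classifier).mask.all()
    assert not apply_classifier(
        uniform_image((225, 210, 222), (24, 24)), separable_classifier
    ).mask.any()


def test_untrained_classifier_refuses_to_predict():
    clf = sq.PixelClassifier()
    with pytest.raises(StainClassificationError, match="not been trained"):
        apply_classifier(uniform_image((0, 0, 0)), clf)


def test_classifier_save_load_round_trip(tmp_path, separable_classifier):
    path = tmp_path / "clf.joblib"
    separable_classifier.save(path)
    back = sq.PixelClassifier.load(path)
    img = uniform_image((135, 85, 45), (16, 16))
    assert np.array_equal(
        apply_classifier(img, back).mask, apply_classifier(img, separable_classifier).mask
    )


def test_classifier_agrees_with_ground_truth_on_section(default_cohort, cohort_classifier):
    """Trained on the section's palette, the classifier matches the painted
    stain mask on >= 98% of all pixels and >= 95% of stained-region pixels
    (where the threshold route is exact)."""
    image, gt = default_cohort[0]
    mask = apply_classifier(image, cohort_classifier).mask
    assert (mask == gt.stain_mask).mean() >= 0.98
    assert mask[gt.stain_mask].mean() >= 0.95
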