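"""Shared fixtures: a calibration, a small fast synthetic section, and the
session-scoped default cohort used by the heavier end-to-end tests."""

from __future__ import annotations

import numpy as np
import pytest

import skinquant as sq
from skinquant.stain import compose_training_image, train_pixel_classifier
from skinquant.synthetic import generate_training_tiles


@pytest.fixture(scope="session")
def calib22() -> sq.ScaleCalibration:
    """The worked-example scale: a 100 um scale bar spanning 220 px."""
    return sq.calibrate_from_scale_bar(220, 100)


@pytest.fixture(scope="session")
def small_params() -> sq.SectionParams:
    """A reduced section for fast unit tests (same scale, smaller extent)."""
    return sq.SectionParams(
        seed=7,
        width_um=220.0,
        epidermis_thickness_um=60.0,
        band_depth_um=120.0,
        apical_offset_um=20.0,
        undulation_amplitude_um=6.0,
        undulation_wavelength_um=150.0,
        bottom_margin_um=15.0,
        n_epidermal_cells=12,
        n_dermal_cells=20,
    )


@pytest.fixture(scope="session")
def small_section(small_params):
    return sq.generate_section(small_params)


@pytest.fixture(scope="session")
def default_cohort():
    """Ten default-condition sections, seeds 1..10."""
    return [sq.generate_section(sq.SectionParams(seed=s)) for s in range(1, 11)]


@pytest.fixture(scope="session")
def cohort_classifier(default_cohort):
    """One pixel classifier trained on tiles from the first cohort section,
    applied to every section (one model per cohort, as in practice)."""
    image, gt = default_cohort[0]
    tiles = generate_training_tiles(image, gt, n_tiles=6, seed=101)
    composite, labels = compose_training_image(tiles)
    return train_pixel_classifier(composite, labels, seed=5)


def dab_spec(gt, tolerance: float = 60.0) -> sq.ColorRangeSpec:
    """Threshold spec picking the section's DAB color."""
    return sq.ColorRangeSpec(reference_colors=(gt.params.palette.dab,), tolerance=tolerance)


def threshold_config(image, gt, sample_id="s", **kw) -> sq.RunConfig:
    """Threshold-mode pipeline config for a synthetic section. The coherence
    dilation is off: the generator's threshold captures painted cells wholly,
    so there is no fragmentation for it to repair."""
    kw.setdefault("coherence_radius_px", 0)
    kw.setdefault("expansion_depth_um", gt.params.band_depth_um)
    return sq.RunConfig(
        sample_id=sample_id,
        image=image,
        annotations=gt.to_annotations(),
        pixels_per_um=image.calibration.pixels_per_um,
        mode="threshold",
        color_spec=dab_spec(gt),
        **kw,
    )


def classifier_config(image, gt, clf, sample_id="s", **kw) -> sq.RunConfig:
    kw.setdefault("expansion_depth_um", gt.params.band_depth_um)
    return sq.RunConfig(
        sample_id=sample_id,
        image=image,
        annotations=gt.to_annotations(),
        pixels_per_um=image.calibration.pixels_per_um,
        mode="classifier",
        classifier=clf,
        **kw,
    )


def gt_density_report(gt, sample_id="gt") -> sq.DensityReport:
    """A density report built directly from generator ground truth."""
    return sq.DensityReport(
        cell_area_um2={c: gt.stained_area_um2(c) for c in ("epidermis", "dermis")},
        cell_count=dict(gt.cell_count),
        compartment_area_um2={
            "epidermis": gt.epidermis_area_um2,
            "dermis": gt.dermis_area_um2,
        },
        epidermal_length_um=gt.epidermal_length_um,
        sample_id=sample_id,
    )


@pytest.fixture(scope="session")
def pair_base_params() -> sq.SectionParams:
    """Non-lesional baseline for NL/LS pairs: sparse infiltrate."""
    return sq.SectionParams(seed=0, n_epidermal_cells=8, n_dermal_cells=24)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
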