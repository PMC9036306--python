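"""Synthetic calibrated skin-section generator with exhaustive ground truth.

Every pipeline stage in this package is testable without slide scans: the
generator draws a horizontally aligned section — slide background above, an
epidermal band whose apical and basal edges follow a smooth periodic
undulation, dermis below — and scatters DAB-brown stained cells as
non-overlapping ellipses in the epidermal and dermal compartments at
requested per-compartment counts. The accompanying :class:`GroundTruth`
records the exact painted stain mask, the per-cell table, compartment masks,
the apical/basal polylines, and pixel-exact areas, so parameter recovery can
be asserted rather than eyeballed.

Constructions chosen for exact bookkeeping:

* the epidermis occupies, in every column, the integer rows in
  ``[f(c), f(c) + t_px)`` with ``t_px`` an integer — exactly ``t_px * width``
  pixels regardless of the undulation phase;
* cell centers sit on integer pixels and ellipse footprints depend only on
  the shape parameters, so replicating a shape list scales the painted area
  exactly (used by :func:`generate_nl_ls_pair` to realize a stain factor);
* cells are placed with a minimum gap (default 3 px) so connected-component
  counting recovers the cell count exactly.

An optional melanin speckle layer (brown hue family, reduced chroma, disabled
by default) exercises the pigment confounder of real sun-exposed skin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Polygon
from skimage.draw import ellipse as draw_ellipse

from .annotations import AnnotationSet
from .calibration import ScaleCalibration
from .errors import SyntheticDataError
from .geometry import Polyline, polyline_length_um
from .images import CalibratedImage

__all__ = ["Palette", "SectionParams", "GroundTruth", "generate_section",
           "generate_nl_ls_pair", "generate_training_tiles"]


@dataclass(frozen=True)
class Palette:
    """Section colors (RGB, 8-bit). Defaults follow DAB-brown chromogen over
    a blue-purple hematoxylin counterstain; numeric values are declared here,
    with no claim of colorimetric fidelity to any scanner."""

    dab: tuple[int, int, int] = (135, 85, 45)
    epidermis: tuple[int, int, int] = (170, 160, 205)
    dermis: tuple[int, int, int] = (225, 210, 222)
    slide: tuple[int, int, int] = (246, 246, 244)
    melanin: tuple[int, int, int] = (95, 75, 60)


@dataclass(frozen=True)
class SectionParams:
    """Study conditions for one synthetic section.

    The scale (2.2 px/um) matches a slide whose 100 um scale bar spans 220
    pixels; the dermal band depth of 400 um and the 100 um thickness are the
    workflow's standard geometry. Cell sizes approximate lymphocytes
    (radius 3.5 +/- 0.7 um, truncated at 2 um).
    """

    seed: int
    width_um: float = 600.0
    pixels_per_um: float = 2.2
    epidermis_thickness_um: float = 100.0
    undulation_amplitude_um: float = 10.0
    undulation_wavelength_um: float = 300.0
    undulation_phase: float | None = None
    apical_offset_um: float = 30.0
    band_depth_um: float = 400.0
    bottom_margin_um: float = 25.0
    n_epidermal_cells: int = 80
    n_dermal_cells: int = 120
    cell_radius_um_mean: float = 3.5
    cell_radius_um_sd: float = 0.7
    cell_radius_um_min: float = 2.0
    max_axis_ratio: float = 1.5
    min_gap_px: float = 3.0
    color_jitter_sd: float = 4.0
    melanin_speckles_per_mm2: float = 0.0
    palette: Palette = field(default_factory=Palette)

    def __post_init__(self) -> None:
        if self.epidermis_thickness_um <= 0 or self.width_um <= 0:
            raise SyntheticDataError("section dimensions must be positive")
        if self.n_epidermal_cells < 0 or self.n_dermal_cells < 0:
            raise SyntheticDataError("cell counts must be nonnegative")
        if self.seed is None:
            raise SyntheticDataError("a seed is mandatory")
        if self.apical_offset_um < self.undulation_amplitude_um:
            raise SyntheticDataError("apical offset must cover the undulation amplitude")

    @property
    def calibration(self) -> ScaleCalibration:
        return ScaleCalibration(self.pixels_per_um)


_CELL_COLUMNS = ["row", "col", "radius_um", "r_row_px", "r_col_px", "rotation",
                 "area_px", "compartment"]


@dataclass
class GroundTruth:
    """Everything the generator knows about a section."""

    stain_mask: np.ndarray
    epidermis_mask: np.ndarray
    dermis_band_mask: np.ndarray
    cells: pd.DataFrame
    apical_polyline: Polyline
    basal_polyline: Polyline
    epidermal_length_um: float
    epidermis_area_um2: float
    dermis_area_um2: float
    stained_area_px: dict[str, int]
    cell_count: dict[str, int]
    thickness_px: int
    band_depth_px: int
    calibration: ScaleCalibration
    params: SectionParams

    def stained_area_um2(self, compartment: str) -> float:
        if compartment == "total":
            return self.calibration.px2_to_um2(sum(self.stained_area_px.values()))
        return self.calibration.px2_to_um2(self.stained_area_px[compartment])

    def compartment_area_um2(self, compartment: str) -> float:
        if compartment == "epidermis":
            return self.epidermis_area_um2
        if compartment == "dermis":
            return self.dermis_area_um2
        if compartment == "total":
            return self.epidermis_area_um2 + self.dermis_area_um2
        raise SyntheticDataError(f"unknown compartment {compartment!r}")

    def to_annotations(self) -> AnnotationSet:
        """The operator annotations a user would have drawn: the epidermis
        outline, the two boundary lines at the section ends, and the apical
        surface polyline."""
        h, w = self.epidermis_mask.shape
        apical = self.apical_polyline.vertices
        basal = self.basal_polyline.vertices
        ring = [(c, r) for r, c in apical] + [(c, r) for r, c in basal[::-1]]
        out = AnnotationSet()
        out.add("epidermis", Polygon(ring), name="epidermis")
        out.add("left_boundary", LineString([(0, 0), (0, h - 1)]), name="left")
        out.add("right_boundary", LineString([(w - 1, 0), (w - 1, h - 1)]), name="right")
        out.add("apical_polyline", LineString([(c, r) for r, c in apical]), name="apical")
        return out


def _sample_shape(rng: np.random.Generator, params: SectionParams) -> dict:
    for _ in range(1000):
        radius = rng.normal(params.cell_radius_um_mean, params.cell_radius_um_sd)
        if radius >= params.cell_radius_um_min:
            break
    else:
        raise SyntheticDataError("could not sample a cell radius above the truncation")
    q = rng.uniform(1.0, params.max_axis_ratio)
    r_px = radius * params.pixels_per_um
    return {
        "radius_um": radius,
        "r_row_px": r_px * math.sqrt(q),
        "r_col_px": r_px / math.sqrt(q),
        "rotation": rng.uniform(0.0, math.pi),
    }


def _place_cells(
    rng: np.random.Generator,
    params: SectionParams,
    f: np.ndarray,
    t_px: int,
    band_px: int,
    shapes_by_compartment: dict[str, list[dict]],
    max_slope: float,
) -> list[dict]:
    w = f.size
    placed_rows: list[float] = []
    placed_cols: list[float] = []
    placed_br: list[float] = []
    cells: list[dict] = []
    for compartment in ("epidermis", "dermis"):
        for shape in shapes_by_compartment[compartment]:
            br = max(shape["r_row_px"], shape["r_col_px"])
            margin = br * (1.0 + max_slope) + 2.0
            m = int(math.ceil(margin))
            for _ in range(400):
                col = int(rng.integers(m, w - m))
                fc = f[col]
                if compartment == "epidermis":
                    lo = int(math.ceil(fc + margin))
                    hi = int(math.floor(fc + t_px - margin))
                else:
                    lo = int(math.ceil(fc + t_px + margin))
                    hi = int(math.floor(fc + t_px + band_px - margin))
                if hi < lo:
                    continue
                row = int(rng.integers(lo, hi + 1))
                if placed_rows:
                    d = np.hypot(np.asarray(placed_rows) - row, np.asarray(placed_cols) - col)
                    if np.any(d < np.asarray(placed_br) + br + params.min_gap_px):
                        continue
                placed_rows.append(row)
                placed_cols.append(col)
                placed_br.append(br)
                cells.append({**shape, "row": row, "col": col, "compartment": compartment})
                break
            else:
                raise SyntheticDataError(
                    f"cell density too high: could not place {compartment} cell "
                    f"{len(cells) + 1} without overlap"
                )
    return cells


def generate_section(
    params: SectionParams, _shape_library: dict[str, list[dict]] | None = None
) -> tuple[CalibratedImage, GroundTruth]:
    """Draw one section. Deterministic for a fixed ``params`` (including its
    seed). ``_shape_library`` lets :func:`generate_nl_ls_pair` replicate cell
    shapes between the members of a pair."""
    rng = np.random.default_rng(params.seed)
    phase = params.undulation_phase
    if phase is None:
        phase = float(rng.uniform(0.0, 2.0 * math.pi))
    ppum = params.pixels_per_um
    w = round(params.width_um * ppum)
    t_px = max(1, round(params.epidermis_thickness_um * ppum))
    band_px = max(1, round(params.band_depth_um * ppum))
    amp_px = params.undulation_amplitude_um * ppum
    lam_px = params.undulation_wavelength_um * ppum
    a0_px = round(params.apical_offset_um * ppum)
    max_slope = 2.0 * math.pi * amp_px / lam_px if lam_px > 0 else 0.0
    slope_extra = band_px * (math.sqrt(1.0 + max_slope**2) - 1.0)
    h = int(
        math.ceil(
            a0_px + amp_px + t_px + band_px + slope_extra
            + params.bottom_margin_um * ppum
        )
    )
    cols = np.arange(w)
    f = a0_px + amp_px * np.sin(2.0 * math.pi * cols / lam_px + phase)

    r_grid = np.arange(h)[:, None]
    epi_mask = (r_grid >= f[None, :]) & (r_grid < f[None, :] + t_px)
    band_mask = (r_grid >= f[None, :] + t_px) & (r_grid < f[None, :] + t_px + band_px)

    if _shape_library is None:
        shapes = {
            "epidermis": [_sample_shape(rng, params) for _ in range(params.n_epidermal_cells)],
            "dermis": [_sample_shape(rng, params) for _ in range(params.n_dermal_cells)],
        }
    else:
        shapes = _shape_library
    cells = _place_cells(rng, params, f, t_px, band_px, shapes, max_slope)

    stain_mask = np.zeros((h, w), dtype=bool)
    stained_px = {"epidermis": 0, "dermis": 0}
    records = []
    for cell in cells:
        rr, cc = draw_ellipse(
            cell["row"], cell["col"], cell["r_row_px"], cell["r_col_px"],
            rotation=cell["rotation"],
        )
        stain_mask[rr, cc] = True
        npix = int(rr.size)
        stained_px[cell["compartment"]] += npix
        records.append({**cell, "area_px": npix})
    cell_table = pd.DataFrame.from_records(records, columns=_CELL_COLUMNS)

    pal = params.palette
    image = np.empty((h, w, 3), dtype=np.float64)
    image[:] = pal.slide
    image[epi_mask] = pal.epidermis
    below = r_grid >= f[None, :] + t_px
    image[below] = pal.dermis
    if params.melanin_speckles_per_mm2 > 0:
        epi_area_mm2 = (t_px * w / ppum**2) / 1e6
        n_speckles = int(rng.poisson(params.melanin_speckles_per_mm2 * epi_area_mm2))
        for _ in range(n_speckles):
            col = int(rng.integers(2, w - 2))
            row = int(rng.integers(int(math.ceil(f[col])) + 2, int(f[col]) + t_px - 2))
            rr, cc = draw_ellipse(row, col, 1.5, 1.5, shape=(h, w))
            image[rr, cc] = pal.melanin
    image[stain_mask] = pal.dab
    if params.color_jitter_sd > 0:
        image = image + rng.normal(0.0, params.color_jitter_sd, size=image.shape)
    pixels = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    calib = params.calibration
    apical = Polyline(np.column_stack([f, cols.astype(float)]))
    basal = Polyline(np.column_stack([f + t_px, cols.astype(float)]))
    counts = {
        "epidermis": int((cell_table["compartment"] == "epidermis").sum()),
        "dermis": int((cell_table["compartment"] == "dermis").sum()),
    }
    gt = GroundTruth(
        stain_mask=stain_mask,
        epidermis_mask=epi_mask,
        dermis_band_mask=band_mask,
        cells=cell_table,
        apical_polyline=apical,
        basal_polyline=basal,
        epidermal_length_um=polyline_length_um(apical, calib),
        epidermis_area_um2=calib.px2_to_um2(float(t_px) * w),
        dermis_area_um2=calib.px2_to_um2(float(band_px) * w),
        stained_area_px=stained_px,
        cell_count=counts,
        thickness_px=t_px,
        band_depth_px=band_px,
        calibration=calib,
        params=params,
    )
    return CalibratedImage(pixels=pixels, calibration=calib), gt


def generate_nl_ls_pair(
    base: SectionParams,
    acanthosis_factor: float = 3.0,
    density_factor: float = 10.0,
    seed: int = 0,
) -> tuple[tuple[CalibratedImage, GroundTruth], tuple[CalibratedImage, GroundTruth]]:
    """Generate a paired non-lesional / lesional section.

    The lesional section has ``acanthosis_factor`` times the epidermal
    thickness at equal epidermal length (the undulation phase is shared), and
    ``density_factor`` times the stained area, realized by scaling the cell
    count and replicating the non-lesional cell shapes so the painted-pixel
    ratio is exact whenever ``density_factor`` times the counts is integral.
    ``base`` describes the non-lesional member; its default-ish counts should
    be low (non-lesional skin carries few target cells).
    """
    if acanthosis_factor < 1:
        raise SyntheticDataError("acanthosis factor must be >= 1")
    if density_factor < 0:
        raise SyntheticDataError("density factor must be >= 0")
    rng = np.random.default_rng(seed)
    phase = float(rng.uniform(0.0, 2.0 * math.pi))
    seed_nl, seed_ls = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    params_nl = replace(base, seed=seed_nl, undulation_phase=phase)
    img_nl, gt_nl = generate_section(params_nl)

    def _tiled(compartment: str, n: int) -> list[dict]:
        src = gt_nl.cells[gt_nl.cells["compartment"] == compartment]
        shapes = src[["radius_um", "r_row_px", "r_col_px", "rotation"]].to_dict("records")
        if not shapes:
            return []
        return [shapes[i % len(shapes)] for i in range(n)]

    n_epi_ls = round(density_factor * base.n_epidermal_cells)
    n_derm_ls = round(density_factor * base.n_dermal_cells)
    params_ls = replace(
        base,
        seed=seed_ls,
        undulation_phase=phase,
        epidermis_thickness_um=base.epidermis_thickness_um * acanthosis_factor,
        n_epidermal_cells=n_epi_ls,
        n_dermal_cells=n_derm_ls,
    )
    img_ls, gt_ls = generate_section(
        params_ls,
        _shape_library={"epidermis": _tiled("epidermis", n_epi_ls),
                        "dermis": _tiled("dermis", n_derm_ls)},
    )
    return (img_nl, gt_nl), (img_ls, gt_ls)


def generate_training_tiles(
    image: CalibratedImage,
    gt: GroundTruth,
    n_tiles: int,
    tile_um: float = 100.0,
    seed: int = 0,
):
    """Sample square training tiles (default 100 x 100 um) from a generated
    section, labeling pixels positive/negative from the ground-truth stain
    mask. At least one tile contains positive pixels and at least one
    contains none. Deterministic for a fixed seed."""
    from .stain import TrainingTile

    if n_tiles < 2:
        raise SyntheticDataError("need at least 2 training tiles")
    if not gt.stain_mask.any():
        raise SyntheticDataError("section has no positive pixels to train on")
    rng = np.random.default_rng(seed)
    h, w = image.shape
    tile_px = round(tile_um * image.calibration.pixels_per_um)
    if tile_px > min(h, w):
        raise SyntheticDataError("tile does not fit inside the section")
    n_pos = max(1, n_tiles // 2)
    tiles = []
    cell_idx = rng.choice(len(gt.cells), size=min(n_pos, len(gt.cells)), replace=False)
    for i in np.atleast_1d(cell_idx):
        cell = gt.cells.iloc[int(i)]
        r0 = int(np.clip(int(cell["row"]) - tile_px // 2, 0, h - tile_px))
        c0 = int(np.clip(int(cell["col"]) - tile_px // 2, 0, w - tile_px))
        tiles.append((r0, c0))
    # fill the remaining slots with stain-free tiles so the negative class is
    # always represented
    attempts = 0
    while len(tiles) < n_tiles:
        attempts += 1
        if attempts > 2000:
            raise SyntheticDataError("could not find enough stain-free training tiles")
        r0 = int(rng.integers(0, h - tile_px + 1))
        c0 = int(rng.integers(0, w - tile_px + 1))
        if not gt.stain_mask[r0 : r0 + tile_px, c0 : c0 + tile_px].any():
            tiles.append((r0, c0))
    out = []
    for r0, c0 in tiles:
        crop_px = image.pixels[r0 : r0 + tile_px, c0 : c0 + tile_px]
        crop_stain = gt.stain_mask[r0 : r0 + tile_px, c0 : c0 + tile_px]
        labels = np.where(crop_stain, 1, 2).astype(np.int8)
        out.append(
            TrainingTile(
                pixels=crop_px.copy(),
                labels=labels,
                side_um=tile_um,
                calibration=image.calibration,
            )
        )
    return out
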