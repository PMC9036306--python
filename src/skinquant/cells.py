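"""Turn positive-stain masks and point annotations into per-compartment
stained areas and cell counts.

A "cell" is operationally a connected component of the positive mask that
passes the size filter; touching stained cells are counted as one component
(no watershed splitting). A component straddling the epidermis/dermis border
is *counted* in the compartment containing its centroid, while stained *area*
always splits exactly by pixel membership, so areas stay conserved and counts
stay integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .calibration import ScaleCalibration
from .errors import QuantificationError
from .geometry import CompartmentSet
from .stain import PositiveMask

__all__ = [
    "CellSet",
    "CountAnnotation",
    "default_min_area_px",
    "split_mask_by_compartment",
    "label_cells",
    "count_points",
    "grid_subsample",
    "GridSelection",
]

CELL_TABLE_COLUMNS = [
    "id",
    "area_px",
    "area_um2",
    "centroid_row",
    "centroid_col",
    "circularity",
    "compartment",
]


@dataclass
class CellSet:
    """Labeled cells: a dense label image (0 = background, ids 1..N) plus one
    record per cell with area, centroid, circularity (4*pi*area/perimeter^2)
    and compartment tag."""

    labels: np.ndarray
    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    def counts_by_compartment(self) -> dict[str, int]:
        counts = self.table["compartment"].value_counts().to_dict()
        return {k: int(counts.get(k, 0)) for k in ("epidermis", "dermis", "outside")}

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class CountAnnotation:
    """Manual click-to-count points, (row, col) pixel coordinates."""

    points: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)


def default_min_area_px(calib: ScaleCalibration, diameter_um: float = 2.0) -> int:
    """Default debris filter: the pixel area of a disk of the given diameter
    (2 um by default — well below any lymphocyte)."""
    r_px = calib.um_to_px(diameter_um / 2.0)
    return max(1, round(math.pi * r_px**2))


def split_mask_by_compartment(
    mask: PositiveMask | np.ndarray, comp: CompartmentSet
) -> dict[str, np.ndarray]:
    """Intersect the positive mask with each compartment mask."""
    m = mask.mask if isinstance(mask, PositiveMask) else np.asarray(mask, dtype=bool)
    if m.shape != comp.shape:
        raise QuantificationError(
            f"mask shape {m.shape} does not match compartments {comp.shape}"
        )
    return {
        "epidermis": m & comp.mask("epidermis"),
        "dermis": m & comp.mask("dermis"),
    }


def label_cells(
    mask: PositiveMask | np.ndarray,
    min_area_px: int = 0,
    max_area_px: int | None = None,
    connectivity: int = 8,
    calibration: ScaleCalibration | None = None,
    compartments: CompartmentSet | None = None,
) -> CellSet:
    """Connected-component labeling with an area filter.

    ``connectivity`` is 4 or 8 (8 by default: diagonal contact joins cells).
    Components with area < ``min_area_px`` or > ``max_area_px`` are dropped;
    surviving cells are relabeled densely 1..N. If ``compartments`` is given,
    each cell is tagged by the compartment containing its centroid pixel.
    """
    m = mask.mask if isinstance(mask, PositiveMask) else np.asarray(mask, dtype=bool)
    if connectivity not in (4, 8):
        raise QuantificationError("connectivity must be 4 or 8")
    if max_area_px is not None and min_area_px > max_area_px:
        raise QuantificationError("min_area_px exceeds max_area_px")
    raw = sk_label(m, connectivity=1 if connectivity == 4 else 2)
    out = np.zeros_like(raw, dtype=np.int32)
    records = []
    next_id = 0
    for prop in regionprops(raw):
        area = int(prop.area)
        if area < min_area_px or (max_area_px is not None and area > max_area_px):
            continue
        next_id += 1
        out[raw == prop.label] = next_id
        perimeter = float(prop.perimeter)
        circularity = 4 * math.pi * area / perimeter**2 if perimeter > 0 else 1.0
        cr, cc = prop.centroid
        compartment = "unassigned"
        if compartments is not None:
            ri, ci = int(round(cr)), int(round(cc))
            ri = min(max(ri, 0), m.shape[0] - 1)
            ci = min(max(ci, 0), m.shape[1] - 1)
            if compartments.mask("epidermis")[ri, ci]:
                compartment = "epidermis"
            elif compartments.dermis_mask is not None and compartments.dermis_mask[ri, ci]:
                compartment = "dermis"
            else:
                compartment = "outside"
        records.append(
            {
                "id": next_id,
                "area_px": area,
                "area_um2": calibration.px2_to_um2(area) if calibration else np.nan,
                "centroid_row": cr,
                "centroid_col": cc,
                "circularity": circularity,
                "compartment": compartment,
            }
        )
    table = pd.DataFrame.from_records(records, columns=CELL_TABLE_COLUMNS)
    return CellSet(labels=out, table=table)


def count_points(points: CountAnnotation, comp: CompartmentSet) -> dict[str, int]:
    """Assign each manual count point to epidermis, dermis, or outside by mask
    membership at its nearest pixel; out-of-bounds points are an error, and
    points landing in neither compartment are reported, not dropped."""
    counts = {"epidermis": 0, "dermis": 0, "outside": 0}
    h, w = comp.shape
    for row, col in points.points:
        ri, ci = int(round(row)), int(round(col))
        if not (0 <= ri < h and 0 <= ci < w):
            raise QuantificationError(f"count point ({row}, {col}) is outside the image")
        if comp.mask("epidermis")[ri, ci]:
            counts["epidermis"] += 1
        elif comp.dermis_mask is not None and comp.dermis_mask[ri, ci]:
            counts["dermis"] += 1
        else:
            counts["outside"] += 1
    return counts


@dataclass
class GridSelection:
    """Result of random-grid subsampling. Squares are identified by their grid
    index ``(i, j)``; square (i, j) covers rows [i*side, (i+1)*side) and the
    matching column range, so every point belongs to exactly one square."""

    side_px: float
    all_squares: list[tuple[int, int]]  # row-major (i, j) of squares touching the ROI
    selected: list[tuple[int, int]]

    @property
    def n_total(self) -> int:
        return len(self.all_squares)

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    def square_index(self, row: float, col: float) -> tuple[int, int]:
        return (int(math.floor(row / self.side_px)), int(math.floor(col / self.side_px)))

    def contains(self, row: float, col: float) -> bool:
        """Whether the point lies in one of the selected squares."""
        return self.square_index(row, col) in set(self.selected)


def grid_subsample(
    roi_mask: np.ndarray,
    calib: ScaleCalibration,
    grid_um: float,
    fraction: float,
    seed: int,
) -> GridSelection:
    """Tile the ROI with axis-aligned squares of side ``grid_um`` and select a
    uniform random subset of ceil(fraction * M) of the M squares that
    intersect the ROI. Deterministic for a fixed seed; counting only inside
    the selected squares and scaling by M/selected gives an unbiased estimate
    of the ROI total."""
    if grid_um <= 0:
        raise QuantificationError("grid_um must be positive")
    if not (0 < fraction <= 1):
        raise QuantificationError("fraction must be in (0, 1]")
    roi = np.asarray(roi_mask, dtype=bool)
    side = calib.um_to_px(grid_um)
    h, w = roi.shape
    squares: list[tuple[int, int]] = []
    n_rows = math.ceil(h / side)
    n_cols = math.ceil(w / side)
    for i in range(n_rows):
        for j in range(n_cols):
            r0 = int(math.ceil(i * side - 1e-9))
            c0 = int(math.ceil(j * side - 1e-9))
            r1 = min(h, int(math.ceil((i + 1) * side)))
            c1 = min(w, int(math.ceil((j + 1) * side)))
            if roi[r0:r1, c0:c1].any():
                squares.append((i, j))
    n_sel = math.ceil(fraction * len(squares))
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(len(squares), size=n_sel, replace=False).tolist())
    return GridSelection(
        side_px=side,
        all_squares=squares,
        selected=[squares[k] for k in chosen],
    )
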