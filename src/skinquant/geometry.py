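"""Tissue-compartment geometry: the epidermal mask, the dermal band derived
from it, boundary clipping, and length/area measurement.

The workflow this mirrors: the operator demarcates the epidermis, the region
is expanded a fixed physical depth (default 400 um) into the dermis — here by
an exact Euclidean distance transform rather than iterated unit dilations —
and the parts apical of the surface polyline or outside the two boundary
lines are discarded. Epidermal length is the arc length of the apical surface
polyline; compartment areas are pixel counts converted through the scale
calibration.

Rasterization convention: a pixel belongs to a polygon if its center lies
inside; centers exactly on an edge count as inside for left/top edges and
outside for right/bottom edges (half-open), so adjacent polygons tile the
grid exactly. Implemented by testing the point nudged by +1e-7 in both axes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import shapely
from scipy.ndimage import distance_transform_edt
from shapely.geometry import LineString, Polygon

from .calibration import ScaleCalibration, um_to_px
from .errors import GeometryError

__all__ = [
    "Polyline",
    "CompartmentSet",
    "build_epidermis_mask",
    "expand_dermal_band",
    "clip_to_boundaries",
    "polyline_length_px",
    "polyline_length_um",
    "estimate_length_by_chords",
    "area_um2",
]

_EDGE_EPS = 1e-7


@dataclass(frozen=True)
class Polyline:
    """Ordered vertices in (row, col) pixel coordinates; >= 2 vertices,
    consecutive vertices distinct."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise GeometryError(f"polyline needs an (N>=2, 2) vertex array, got {v.shape}")
        seg = np.diff(v, axis=0)
        if np.any(np.all(seg == 0, axis=1)):
            raise GeometryError("polyline has repeated consecutive vertices")
        object.__setattr__(self, "vertices", v)

    @classmethod
    def from_shapely(cls, line: LineString) -> "Polyline":
        xy = np.asarray(line.coords, dtype=float)
        return cls(xy[:, ::-1])  # (x, y) -> (row, col)

    def to_shapely(self) -> LineString:
        return LineString(self.vertices[:, ::-1])

    @property
    def rows(self) -> np.ndarray:
        return self.vertices[:, 0]

    @property
    def cols(self) -> np.ndarray:
        return self.vertices[:, 1]


@dataclass
class CompartmentSet:
    """The two quantification compartments and the geometry that bounds them.

    ``epidermis_mask`` and ``dermis_mask`` are disjoint boolean H x W masks;
    the dermis is a band of ``expansion_depth_um`` below the epidermis,
    clipped by the boundary lines and the apical polyline.
    """

    epidermis_mask: np.ndarray
    dermis_mask: np.ndarray | None = None
    left_boundary: Polyline | None = None
    right_boundary: Polyline | None = None
    apical_polyline: Polyline | None = None
    expansion_depth_um: float = 400.0

    def __post_init__(self) -> None:
        self.epidermis_mask = np.asarray(self.epidermis_mask, dtype=bool)
        if self.expansion_depth_um <= 0:
            raise GeometryError("expansion depth must be positive")
        if self.dermis_mask is not None:
            self.dermis_mask = np.asarray(self.dermis_mask, dtype=bool)
            self.check_disjoint()

    @property
    def shape(self) -> tuple[int, int]:
        return self.epidermis_mask.shape

    def check_disjoint(self) -> None:
        if self.dermis_mask is not None and np.any(self.epidermis_mask & self.dermis_mask):
            raise GeometryError("epidermis and dermis masks overlap")

    def mask(self, compartment: str) -> np.ndarray:
        if compartment == "epidermis":
            return self.epidermis_mask
        if compartment == "dermis":
            if self.dermis_mask is None:
                raise GeometryError("dermis mask has not been built yet")
            return self.dermis_mask
        if compartment == "total":
            return self.epidermis_mask | self.mask("dermis")
        raise GeometryError(f"unknown compartment {compartment!r}")


def build_epidermis_mask(polygon: Polygon, image_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize the operator's epidermis polygon: a pixel is inside if its
    center is inside (half-open edge convention, see module docstring)."""
    if not isinstance(polygon, Polygon) or not polygon.is_valid:
        raise GeometryError("epidermis annotation must be a simple polygon")
    if polygon.area <= 0:
        raise GeometryError("degenerate (zero-area) epidermis polygon")
    h, w = int(image_shape[0]), int(image_shape[1])
    minx, miny, maxx, maxy = polygon.bounds
    if maxx < -0.5 or maxy < -0.5 or minx > w - 0.5 or miny > h - 0.5:
        raise GeometryError("polygon lies entirely outside the image")
    # restrict the center test to the polygon's bounding box
    c0, c1 = max(0, int(np.floor(minx))), min(w - 1, int(np.ceil(maxx)))
    r0, r1 = max(0, int(np.floor(miny))), min(h - 1, int(np.ceil(maxy)))
    cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    shapely.prepare(polygon)
    inside = shapely.contains_xy(
        polygon, cols.ravel() + _EDGE_EPS, rows.ravel() + _EDGE_EPS
    ).reshape(rows.shape)
    mask = np.zeros((h, w), dtype=bool)
    mask[r0 : r1 + 1, c0 : c1 + 1] = inside
    return mask


def expand_dermal_band(comp: CompartmentSet, calib: ScaleCalibration) -> CompartmentSet:
    """Derive the dermal compartment: all pixels within the expansion depth
    (exact Euclidean distance) of the epidermis, minus the epidermis itself,
    clipped by whatever boundary geometry the compartment set carries."""
    epi = comp.epidermis_mask
    if not epi.any():
        raise GeometryError("cannot expand an empty epidermis mask")
    depth_px = um_to_px(comp.expansion_depth_um, calib)
    dist = distance_transform_edt(~epi)
    band = (dist <= depth_px + 1e-9) & ~epi
    band = clip_to_boundaries(
        band,
        left_boundary=comp.left_boundary,
        right_boundary=comp.right_boundary,
        apical_polyline=comp.apical_polyline,
    )
    out = replace(comp, dermis_mask=band)
    out.check_disjoint()
    return out


def _boundary_col_at(rows: np.ndarray, line: Polyline, mask_rows: np.ndarray) -> np.ndarray:
    order = np.argsort(line.rows, kind="stable")
    r, c = line.rows[order], line.cols[order]
    if mask_rows.size and (mask_rows.min() < r[0] - 1e-9 or mask_rows.max() > r[-1] + 1e-9):
        raise GeometryError("boundary polyline does not span the mask's vertical extent")
    return np.interp(rows, r, c)


def clip_to_boundaries(
    mask: np.ndarray,
    left_boundary: Polyline | None = None,
    right_boundary: Polyline | None = None,
    apical_polyline: Polyline | None = None,
) -> np.ndarray:
    """Zero out pixels strictly left/right of the boundary lines or on the
    apical (smaller-row) side of the apical polyline.

    Boundary lines are parametrized by row, the apical polyline by column;
    both are linearly interpolated between vertices and extended with their
    end values. Assumes the slide has been aligned horizontally, so "apical"
    means vertically above.
    """
    mask = np.asarray(mask, dtype=bool)
    out = mask.copy()
    if not out.any():
        return out
    h, w = out.shape
    rows = np.arange(h, dtype=float)
    cols = np.arange(w, dtype=float)
    true_rows, true_cols = np.nonzero(mask)
    if left_boundary is not None:
        lc = _boundary_col_at(rows, left_boundary, true_rows)
        out &= cols[None, :] >= lc[:, None] - 1e-9
    if right_boundary is not None:
        rc = _boundary_col_at(rows, right_boundary, true_rows)
        out &= cols[None, :] <= rc[:, None] + 1e-9
    if apical_polyline is not None:
        order = np.argsort(apical_polyline.cols, kind="stable")
        ac = np.interp(cols, apical_polyline.cols[order], apical_polyline.rows[order])
        out &= rows[:, None] >= ac[None, :] - 1e-9
    return out


def polyline_length_px(line: Polyline) -> float:
    """Arc length of a polyline in pixels."""
    seg = np.diff(line.vertices, axis=0)
    return float(np.hypot(seg[:, 0], seg[:, 1]).sum())


def polyline_length_um(line: Polyline, calib: ScaleCalibration) -> float:
    """Arc length of a polyline in micrometres."""
    return calib.px_to_um(polyline_length_px(line))


def estimate_length_by_chords(
    line: Polyline, n_chords: int, calib: ScaleCalibration
) -> float:
    """Estimate polyline length the way it is done with a ruler tool: resample
    the line at ``n_chords + 1`` points equally spaced by arc length and sum
    the straight chords between them. Always <= the true polyline length, and
    converges to it as ``n_chords`` grows."""
    if n_chords < 1:
        raise GeometryError("n_chords must be >= 1")
    v = line.vertices
    seg = np.hypot(*np.diff(v, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, s[-1], n_chords + 1)
    rr = np.interp(targets, s, v[:, 0])
    cc = np.interp(targets, s, v[:, 1])
    chord_sum = float(np.hypot(np.diff(rr), np.diff(cc)).sum())
    return calib.px_to_um(chord_sum)


def area_um2(mask: np.ndarray, calib: ScaleCalibration) -> float:
    """Area of a boolean mask in um^2 (true-pixel count over px/um squared)."""
    return calib.px2_to_um2(float(np.count_nonzero(np.asarray(mask, dtype=bool))))
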