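"""ROI geometry: rasterization vs brute-force point-in-polygon, dermal band
vs enumerated offsets, boundary clipping, and arc-length measurement vs
numeric quadrature."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from shapely.geometry import Polygon

import skinquant as sq
from skinquant.errors import GeometryError
from skinquant.geometry import Polyline, polyline_length_px

UNIT = sq.ScaleCalibration(1.0)
EPS = 1e-7


def raycast_inside(px: float, py: float, poly: list[tuple[float, float]]) -> bool:
    """Independent crossing-number point-in-polygon test, evaluated at the
    package's +eps tie-break point."""
    px, py = px + EPS, py + EPS
    inside = False
    j = len(poly) - 1
    for i in range(len(poly)):
        xi, yi = poly[i]
        xj, yj = poly[j]
        if (yi > py) != (yj > py) and px < (xj - xi) * (py - yi) / (yj - yi) + xi:
            inside = not inside
        j = i
    return inside


def brute_force_mask(coords, shape):
    mask = np.zeros(shape, dtype=bool)
    for r in range(shape[0]):
        for c in range(shape[1]):
            mask[r, c] = raycast_inside(c, r, coords)
    return mask


def test_rectangle_rasterizes_to_exact_area():
    rect = Polygon([(0, 0), (20, 0), (20, 10), (0, 10)])
    mask = sq.build_epidermis_mask(rect, (30, 30))
    assert mask.sum() == 200  # 10 x 20 px, half-open edges


def test_triangle_matches_brute_force_oracle():
    coords = [(0, 0), (0, 4), (4, 0)]
    mask = sq.build_epidermis_mask(Polygon(coords), (8, 8))
    assert np.array_equal(mask, brute_force_mask(coords, (8, 8)))


def test_random_polygons_match_brute_force_oracle():
    rng = np.random.default_rng(3)
    for _ in range(20):
        pts = rng.uniform(1, 19, size=(8, 2))
        hull = Polygon(pts).convex_hull
        coords = list(hull.exterior.coords)[:-1]
        mask = sq.build_epidermis_mask(hull, (20, 20))
        assert np.array_equal(mask, brute_force_mask(coords, (20, 20)))


def test_degenerate_polygon_rejected():
    with pytest.raises(GeometryError):
        sq.build_epidermis_mask(Polygon([(0, 0), (2, 2), (4, 4)]), (10, 10))


def test_polygon_outside_image_rejected():
    with pytest.raises(GeometryError, match="outside"):
        sq.build_epidermis_mask(Polygon([(50, 50), (60, 50), (60, 60)]), (10, 10))


def test_raster_area_near_shoelace_for_convex_polygons():
    """|pixel count - analytic shoelace area| <= perimeter (in px) for 50
    random convex polygons."""
    rng = np.random.default_rng(11)
    for _ in range(50):
        pts = rng.uniform(2, 48, size=(10, 2))
        hull = Polygon(pts).convex_hull
        mask = sq.build_epidermis_mask(hull, (50, 50))
        assert abs(mask.sum() - hull.area) <= hull.length


# --- dermal band -----------------------------------------------------------


def _strip_compartments(h, w, strip_rows, depth_um, calib=UNIT):
    epi = np.zeros((h, w), dtype=bool)
    epi[strip_rows, :] = True
    comp = sq.CompartmentSet(epidermis_mask=epi, expansion_depth_um=depth_um)
    return sq.expand_dermal_band(comp, calib)


def test_flat_strip_band_height():
    comp = _strip_compartments(40, 30, slice(0, 5), depth_um=12)
    heights = comp.dermis_mask.sum(axis=0)
    assert (heights == 12).all()
    assert not (comp.epidermis_mask & comp.dermis_mask).any()


def test_band_reaches_880_px_at_the_printed_scale(calib22):
    epi = np.zeros((1000, 4), dtype=bool)
    epi[0:10, :] = True
    comp = sq.CompartmentSet(epidermis_mask=epi, expansion_depth_um=400.0)
    band = sq.expand_dermal_band(comp, calib22).dermis_mask
    rows = np.nonzero(band.any(axis=1))[0]
    assert rows.max() == 9 + 880  # 400 um = 880 px below the strip's last row


def test_single_pixel_band_is_discrete_disk():
    d = 4
    epi = np.zeros((21, 21), dtype=bool)
    epi[10, 10] = True
    comp = sq.CompartmentSet(epidermis_mask=epi, expansion_depth_um=d)
    band = sq.expand_dermal_band(comp, UNIT).dermis_mask
    expected = {
        (10 + dr, 10 + dc)
        for dr in range(-d, d + 1)
        for dc in range(-d, d + 1)
        if 0 < dr * dr + dc * dc <= d * d
    }
    assert set(zip(*np.nonzero(band))) == expected


def test_band_monotone_in_depth():
    shallow = _strip_compartments(40, 30, slice(3, 8), depth_um=5).dermis_mask
    deep = _strip_compartments(40, 30, slice(3, 8), depth_um=11).dermis_mask
    assert (shallow <= deep).all()


def test_empty_epidermis_rejected(calib22):
    comp = sq.CompartmentSet(epidermis_mask=np.zeros((5, 5), dtype=bool))
    with pytest.raises(GeometryError, match="empty"):
        sq.expand_dermal_band(comp, calib22)


# --- boundary clipping -----------------------------------------------------


def _vline(col, h):
    return Polyline([(0, col), (h - 1, col)])


def test_clip_to_vertical_boundaries():
    mask = np.ones((20, 100), dtype=bool)
    out = sq.clip_to_boundaries(mask, left_boundary=_vline(10, 20),
                                right_boundary=_vline(90, 20))
    cols = np.nonzero(out.any(axis=0))[0]
    assert cols.min() == 10 and cols.max() == 90


def test_apical_polyline_above_mask_is_no_op():
    mask = np.zeros((20, 10), dtype=bool)
    mask[10:15, :] = True
    apical = Polyline([(2.0, 0.0), (2.0, 9.0)])
    assert np.array_equal(sq.clip_to_boundaries(mask, apical_polyline=apical), mask)


def test_apical_clip_removes_rows_above():
    mask = np.ones((20, 10), dtype=bool)
    apical = Polyline([(5.0, 0.0), (5.0, 9.0)])
    out = sq.clip_to_boundaries(mask, apical_polyline=apical)
    assert not out[:5, :].any() and out[5:, :].all()


def test_clip_of_empty_mask_is_empty():
    mask = np.zeros((6, 6), dtype=bool)
    assert not sq.clip_to_boundaries(mask, left_boundary=_vline(2, 6)).any()


def test_boundary_must_span_mask():
    mask = np.ones((20, 10), dtype=bool)
    short = Polyline([(5, 3), (10, 3)])
    with pytest.raises(GeometryError, match="span"):
        sq.clip_to_boundaries(mask, left_boundary=short)


# --- lengths and areas -----------------------------------------------------


def sine_polyline(n=1000):
    x = np.linspace(0, 2 * math.pi, n)
    return Polyline(np.column_stack([np.sin(x), x]))


def sine_arc_length():
    return quad(lambda x: math.sqrt(1 + math.cos(x) ** 2), 0, 2 * math.pi)[0]


def test_polyline_length_345():
    assert sq.polyline_length_um(Polyline([(0, 0), (3, 4)]), UNIT) == pytest.approx(5.0)


def test_closed_square_polyline_length():
    square = Polyline([(0, 0), (0, 10), (10, 10), (10, 0), (0, 0)])
    assert sq.polyline_length_um(square, UNIT) == pytest.approx(40.0)


def test_polyline_needs_two_distinct_vertices():
    with pytest.raises(GeometryError):
        Polyline([(1, 1)])
    with pytest.raises(GeometryError):
        Polyline([(1, 1), (1, 1)])


def test_sine_length_matches_quadrature():
    assert sq.polyline_length_um(sine_polyline(), UNIT) == pytest.approx(
        sine_arc_length(), rel=1e-3
    )


def test_chord_estimate_straight_line_exact():
    line = Polyline([(0, 0), (30, 40)])
    for n in (1, 2, 7):
        assert sq.estimate_length_by_chords(line, n, UNIT) == pytest.approx(50.0)


def test_chord_estimate_monotone_and_bounded():
    line = sine_polyline()
    full = sq.polyline_length_um(line, UNIT)
    estimates = [sq.estimate_length_by_chords(line, n, UNIT) for n in (5, 10, 20, 50, 100, 200)]
    assert all(a <= b + 1e-12 for a, b in zip(estimates, estimates[1:]))
    assert all(e <= full + 1e-12 for e in estimates)
    assert estimates[-1] == pytest.approx(sine_arc_length(), rel=1e-2)


@pytest.mark.parametrize(
    "n_true, ppum, expected",
    [(100, 2.0, 25.0), (0, 2.0, 0.0), (220 * 220, 2.2, 10_000.0)],
)
def test_area_um2(n_true, ppum, expected):
    mask = np.zeros(48400, dtype=bool)
    mask[:n_true] = True
    assert sq.area_um2(mask.reshape(220, 220), sq.ScaleCalibration(ppum)) == pytest.approx(
        expected
    )


def test_compartments_disjoint_and_additive(small_section, calib22):
    _, gt = small_section
    comp = sq.CompartmentSet(
        epidermis_mask=gt.epidermis_mask,
        apical_polyline=gt.apical_polyline,
        expansion_depth_um=gt.params.band_depth_um,
    )
    comp = sq.expand_dermal_band(comp, gt.calibration)
    assert not (comp.epidermis_mask & comp.dermis_mask).any()
    total = sq.area_um2(comp.mask("total"), gt.calibration)
    assert total == pytest.approx(
        sq.area_um2(comp.epidermis_mask, gt.calibration)
        + sq.area_um2(comp.dermis_mask, gt.calibration)
    )
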