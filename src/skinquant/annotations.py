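"""Operator annotations carried as GeoJSON.

Annotations are the manual inputs of the workflow: the painted epidermis
outline, the two boundary lines orthogonal to the skin surface, the apical
surface polyline used for length measurement, training tiles for the pixel
classifier, and manual point counts. They are exchanged as a GeoJSON
FeatureCollection (the format the QuPath ecosystem also emits), with each
feature carrying a ``role`` property from :data:`ROLES`.

GeoJSON coordinates are ``(x, y) = (col, row)`` in pixel units; polygons are
written as closed, counterclockwise rings.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, MultiPoint, Point, Polygon, mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.geometry.polygon import orient

from .errors import AnnotationError

__all__ = ["ROLES", "Annotation", "AnnotationSet", "read_annotations", "write_annotations"]

ROLES = frozenset(
    {
        "epidermis",
        "left_boundary",
        "right_boundary",
        "apical_polyline",
        "training_tile",
        "point_count",
        "mask_edit",
    }
)


def _validate_geometry(role: str, geom: BaseGeometry) -> BaseGeometry:
    if role not in ROLES:
        raise AnnotationError(f"unknown role label {role!r}; expected one of {sorted(ROLES)}")
    if isinstance(geom, Polygon):
        if not geom.is_valid:
            raise AnnotationError(f"non-simple polygon for role {role!r}")
        if geom.area <= 0:
            raise AnnotationError(f"degenerate (zero-area) polygon for role {role!r}")
        geom = orient(Polygon(geom.exterior.coords, [r.coords for r in geom.interiors]), 1.0)
    elif isinstance(geom, LineString):
        if len(geom.coords) < 2:
            raise AnnotationError(f"polyline for role {role!r} needs at least 2 vertices")
    elif isinstance(geom, (Point, MultiPoint)):
        pass
    else:
        raise AnnotationError(f"unsupported geometry type {geom.geom_type} for role {role!r}")
    return geom


@dataclass
class Annotation:
    role: str
    geometry: BaseGeometry
    name: str | None = None
    properties: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.geometry = _validate_geometry(self.role, self.geometry)


@dataclass
class AnnotationSet:
    """A named collection of role-labeled geometries in pixel coordinates."""

    annotations: list[Annotation] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.annotations)

    def __iter__(self):
        return iter(self.annotations)

    def add(self, role: str, geometry: BaseGeometry, name: str | None = None, **props) -> None:
        self.annotations.append(Annotation(role, geometry, name, dict(props)))

    def by_role(self, role: str) -> list[Annotation]:
        return [a for a in self.annotations if a.role == role]

    def first(self, role: str) -> Annotation | None:
        found = self.by_role(role)
        return found[0] if found else None

    def points(self, role: str = "point_count") -> np.ndarray:
        """All point annotations of a role as an (N, 2) array of (row, col)."""
        pts: list[tuple[float, float]] = []
        for a in self.by_role(role):
            geom = a.geometry
            if isinstance(geom, Point):
                pts.append((geom.y, geom.x))
            elif isinstance(geom, MultiPoint):
                pts.extend((p.y, p.x) for p in geom.geoms)
        return np.asarray(pts, dtype=float).reshape(-1, 2)


def read_annotations(path: str | os.PathLike) -> AnnotationSet:
    """Read a GeoJSON FeatureCollection of role-labeled annotations."""
    with open(os.fspath(path)) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise AnnotationError(f"{path}: expected a GeoJSON FeatureCollection")
    out = AnnotationSet()
    for feat in doc.get("features", []):
        props = dict(feat.get("properties") or {})
        role = props.pop("role", None)
        if role is None:
            raise AnnotationError(f"{path}: feature without a 'role' property")
        name = props.pop("name", None)
        out.annotations.append(Annotation(role, shape(feat["geometry"]), name, props))
    return out


def write_annotations(aset: AnnotationSet, path: str | os.PathLike) -> None:
    """Write an AnnotationSet as GeoJSON; write->read round trips preserve
    geometry to well below 1e-6 px (coordinates are serialized at full float
    precision)."""
    features = []
    for a in aset:
        props = {"role": a.role, **a.properties}
        if a.name is not None:
            props["name"] = a.name
        features.append(
            {"type": "Feature", "geometry": mapping(a.geometry), "properties": props}
        )
    doc = {"type": "FeatureCollection", "features": features}
    with open(os.fspath(path), "w") as fh:
        json.dump(doc, fh)
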