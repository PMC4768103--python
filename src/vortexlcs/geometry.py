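"""Planar-polygon helpers shared by contour handling, delineation and volumetrics.

All vertices are world coordinates in mm. Polygons are stored *open* (the
closing edge from the last back to the first vertex is implicit). Short-axis
slices are planes of constant z, so 2-D set operations (intersection, union)
project onto the x-y plane; areas of arbitrary planar polygons are computed
with the 3-D shoelace formula, which is orientation- and vertex-order
invariant.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union


def strip_closing_vertex(vertices: np.ndarray) -> np.ndarray:
    """Return the polygon with an explicit duplicate closing vertex removed."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2:
        raise ValueError("polygon vertices must be a 2-D array")
    if len(v) > 1 and np.allclose(v[0], v[-1]):
        v = v[:-1]
    return v


def polygon_area(vertices: np.ndarray) -> float:
    """Area (mm^2) of a planar polygon in 3-D, via the vector shoelace formula.

    Independent of vertex orientation and of which vertex comes first; returns
    0 for degenerate (<3 distinct vertices) input.
    """
    v = strip_closing_vertex(vertices)
    if len(v) < 3:
        return 0.0
    if v.shape[1] == 2:
        v = np.column_stack([v, np.zeros(len(v))])
    d = v - v.mean(axis=0)
    cross = np.cross(d, np.roll(d, -1, axis=0))
    return float(0.5 * np.linalg.norm(cross.sum(axis=0)))


def to_shapely(polygons: list[np.ndarray]):
    """Union of planar polygons as a shapely geometry in the x-y plane.

    Minor self-intersections (e.g. from bridged ridge arcs) are repaired with
    ``buffer(0)``. Overlapping polygons are unioned, never double counted.
    """
    geoms = []
    for verts in polygons:
        v = strip_closing_vertex(verts)
        if len(v) < 3:
            continue
        p = Polygon(v[:, :2])
        if not p.is_valid:
            p = p.buffer(0)
        if not p.is_empty:
            geoms.append(p)
    if not geoms:
        return Polygon()
    return unary_union(geoms)


def from_shapely(geom, z: float) -> list[np.ndarray]:
    """Convert a shapely (Multi)Polygon back to a list of (N, 3) contours at height z."""
    if geom.is_empty:
        return []
    if isinstance(geom, Polygon):
        parts = [geom]
    elif isinstance(geom, MultiPolygon):
        parts = list(geom.geoms)
    else:  # GeometryCollection from a degenerate intersection
        parts = [g for g in getattr(geom, "geoms", []) if isinstance(g, Polygon)]
    out = []
    for p in parts:
        xy = np.asarray(p.exterior.coords)[:-1]  # drop shapely's closing vertex
        if len(xy) >= 3:
            out.append(np.column_stack([xy, np.full(len(xy), z)]))
    return out


def union_area(polygons: list[np.ndarray]) -> float:
    """Area (mm^2) of the union of coplanar polygons (x-y plane projection)."""
    return float(to_shapely(polygons).area)


def effective_diameter(area_mm2: float) -> float:
    """Diameter (mm) of the circle with the given area: 2*sqrt(A/pi)."""
    if area_mm2 < 0:
        raise ValueError("area must be non-negative")
    return float(2.0 * np.sqrt(area_mm2 / np.pi))


def circle_polygon(center_xy, radius: float, z: float, n: int = 72) -> np.ndarray:
    """Regular-polygon approximation of a circle, as an (n, 3) contour."""
    ang = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack(
        [
            center_xy[0] + radius * np.cos(ang),
            center_xy[1] + radius * np.sin(ang),
            np.full(n, z),
        ]
    )


def ellipse_polygon(center_xy, semi_x: float, semi_y: float, z: float, n: int = 72) -> np.ndarray:
    ang = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack(
        [
            center_xy[0] + semi_x * np.cos(ang),
            center_xy[1] + semi_y * np.sin(ang),
            np.full(n, z),
        ]
    )
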