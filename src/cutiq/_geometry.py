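"""Planar geometry helpers for polyline traces.

Coordinates follow raster conventions: x rightward (column), y downward
(row), origin at the center of the top-left pixel, sub-pixel positions
allowed. All functions work on ``(n, 2)`` float arrays of ``[x, y]`` points.
"""
from __future__ import annotations

import numpy as np
from matplotlib.path import Path as _MplPath

from .exceptions import GeometryError

#: unit vector declared by each orientation flag (the side of the interface
#: on which the cuticle lies)
ORIENTATION_VECTORS = {
    "increasing-y": np.array([0.0, 1.0]),
    "decreasing-y": np.array([0.0, -1.0]),
    "increasing-x": np.array([1.0, 0.0]),
    "decreasing-x": np.array([-1.0, 0.0]),
}


def as_points(obj) -> np.ndarray:
    pts = np.asarray(obj, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise GeometryError(f"expected an (n, 2) point array, got shape {pts.shape}")
    return pts


def cumulative_arclength(points: np.ndarray) -> np.ndarray:
    """Cumulative arc length at each vertex, starting at 0."""
    points = as_points(points)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_polyline(points: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at (approximately) uniform arc-length steps.

    Returns ``(resampled_points, arclengths)``; endpoints are preserved
    exactly and the actual step is ``total / (n - 1) <= step``.
    """
    points = as_points(points)
    if len(points) < 2:
        raise GeometryError("polyline needs at least 2 points")
    s = cumulative_arclength(points)
    total = s[-1]
    if total <= 0:
        raise GeometryError("polyline has zero length")
    n = max(int(np.ceil(total / step)) + 1, 2)
    si = np.linspace(0.0, total, n)
    x = np.interp(si, s, points[:, 0])
    y = np.interp(si, s, points[:, 1])
    return np.column_stack([x, y]), si


def unit_tangents(points: np.ndarray) -> np.ndarray:
    """Central-difference unit tangents along a polyline (one-sided at ends)."""
    g = np.gradient(as_points(points), axis=0)
    norms = np.linalg.norm(g, axis=1)
    if np.any(norms <= 0):
        raise GeometryError("degenerate (zero-length) tangent on polyline")
    return g / norms[:, None]


def normals_toward(tangents: np.ndarray, orientation: str) -> np.ndarray:
    """Rotate tangents 90 degrees toward the side declared by *orientation*.

    The rotation sign is chosen globally (from the mean normal) so that a
    curved interface keeps a continuous normal field even where individual
    normals are momentarily perpendicular to the declared axis.
    """
    try:
        vec = ORIENTATION_VECTORS[orientation]
    except KeyError:
        raise GeometryError(f"unknown orientation flag {orientation!r}") from None
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    score = float(np.mean(normals @ vec))
    if score == 0.0:
        raise GeometryError(
            "interface normals are perpendicular to the declared orientation axis"
        )
    return -normals if score < 0 else normals


def ray_polyline_intersections(
    origin: np.ndarray,
    direction: np.ndarray,
    polyline: np.ndarray,
    t_min: float = 1e-9,
) -> np.ndarray:
    """Sorted ray parameters ``t > t_min`` where ``origin + t*direction``
    crosses the polyline. Parallel segments yield no intersection."""
    poly = as_points(polyline)
    o = np.asarray(origin, float)
    r = np.asarray(direction, float)
    p = poly[:-1]
    s = poly[1:] - poly[:-1]
    denom = r[0] * s[:, 1] - r[1] * s[:, 0]  # cross(r, s)
    w = p - o
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (w[:, 0] * s[:, 1] - w[:, 1] * s[:, 0]) / denom  # cross(w, s)/denom
        u = (w[:, 0] * r[1] - w[:, 1] * r[0]) / denom  # cross(w, r)/denom
    ok = (np.abs(denom) > 1e-12) & (u >= -1e-9) & (u <= 1 + 1e-9) & (t > t_min)
    return np.sort(t[ok])


def first_hit(origin, direction, polyline, t_min: float = 1e-9):
    """Distance along the ray to its first crossing of *polyline*, or None."""
    hits = ray_polyline_intersections(origin, direction, polyline, t_min=t_min)
    return float(hits[0]) if hits.size else None


def polygon_signed_area(polygon: np.ndarray) -> float:
    """Shoelace signed area (px^2) of a polygon given by its vertices."""
    p = as_points(polygon)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_pixel_mask(polygon: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers lie inside the polygon.

    *shape* is the raster shape ``(rows, cols)``; pixel centers sit at
    integer coordinates.
    """
    poly = as_points(polygon)
    rows, cols = shape
    c0 = max(int(np.floor(poly[:, 0].min())), 0)
    c1 = min(int(np.ceil(poly[:, 0].max())), cols - 1)
    r0 = max(int(np.floor(poly[:, 1].min())), 0)
    r1 = min(int(np.ceil(poly[:, 1].max())), rows - 1)
    mask = np.zeros(shape, dtype=bool)
    if c1 < c0 or r1 < r0:
        return mask
    cc, rr = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    centers = np.column_stack([cc.ravel(), rr.ravel()])
    inside = _MplPath(poly).contains_points(centers)
    mask[rr.ravel()[inside], cc.ravel()[inside]] = True
    return mask
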