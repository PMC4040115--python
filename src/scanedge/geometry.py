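"""Distance-to-edge geometry: the medial depth D and edge coefficients.

The edge coefficient of a point at distance ``d`` from the region boundary is

    eps = 1 - 2 d / D,

where ``D`` is the depth of the region: the largest Euclidean distance from any
interior point to the boundary.  The deepest point lies on the medial axis (the
locus of interior points with more than one nearest boundary point), and ``D``
equals the radius of the largest inscribed circle.  ``eps`` is +1 exactly on
the boundary, -1 at the deepest medial point, and decreases strictly with
depth; it is scale-invariant.

``D`` is found by evaluating the distance-to-boundary field on a regular grid
and refining the best grid point with a derivative-free local search, which
guarantees the result within one grid step of the true value.  Holes in the
region count as boundary, and in a multi-part region each component gets its
own ``D`` so that ``eps`` reaches -1 inside every component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy.optimize import minimize
from shapely.geometry import MultiPolygon, Point, Polygon
from shapely.geometry.base import BaseGeometry

from .region import Region

__all__ = [
    "EdgeCoefficients",
    "distance_to_edge",
    "medial_depth",
    "edge_coefficients",
    "edge_coefficient_field",
]


@dataclass(frozen=True)
class EdgeCoefficients:
    """Per-SU distances to the edge, the depth scale and edge coefficients.

    Attributes
    ----------
    d : (n,) array
        Minimal Euclidean distance from each SU centroid to the region boundary.
    depth : float or (n,) array
        The depth scale D.  A scalar for a single-component region; per-SU
        values when components have different depths.
    epsilon : (n,) array
        Edge coefficients ``1 - 2 d / D``, each in [-1, 1].
    """

    d: np.ndarray
    depth: float | np.ndarray
    epsilon: np.ndarray


def distance_to_edge(point: tuple[float, float], boundary: BaseGeometry) -> float:
    """Minimal Euclidean distance from an interior point to the region boundary.

    Raises ``ValueError`` when the point lies outside the region (the edge
    coefficient is only defined inside).  Returns 0 for points on the boundary.
    """
    p = Point(point)
    if not boundary.covers(p):
        raise ValueError(f"point {tuple(point)} lies outside the region boundary")
    return float(p.distance(boundary.boundary))


def _signed_distance(xy: np.ndarray, polygon: BaseGeometry) -> float:
    # positive inside, negative outside: lets the local search stay interior
    p = Point(xy)
    d = p.distance(polygon.boundary)
    return d if polygon.covers(p) else -d


def _grid_depth(polygon: BaseGeometry, resolution: float) -> tuple[np.ndarray, float]:
    minx, miny, maxx, maxy = polygon.bounds
    xs = np.arange(minx + resolution / 2, maxx, resolution)
    ys = np.arange(miny + resolution / 2, maxy, resolution)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("polygon is degenerate at this resolution")
    gx, gy = np.meshgrid(xs, ys)
    flat = np.column_stack([gx.ravel(), gy.ravel()])
    inside = shapely.contains_xy(polygon, flat[:, 0], flat[:, 1])
    if not inside.any():
        # thin polygon: fall back to its representative interior point
        rp = polygon.representative_point()
        return np.array([rp.x, rp.y]), float(rp.distance(polygon.boundary))
    pts = shapely.points(flat[inside])
    dists = shapely.distance(pts, polygon.boundary)
    k = int(np.argmax(dists))
    return flat[inside][k], float(dists[k])


def medial_depth(
    boundary: BaseGeometry, resolution: float | None = None
) -> float:
    """Depth D of a region: the maximal distance from an interior point to the edge.

    Equivalently the deepest point of the medial axis, or the radius of the
    maximal inscribed circle.  Evaluated on a regular grid of spacing
    ``resolution`` (default: bounding-box diagonal / 2000) and refined by
    Nelder–Mead from the best grid point, so the result is within one
    resolution step of the true value.  Multi-part geometries return the depth
    of the deepest component; use :func:`edge_coefficients` for per-component
    handling.
    """
    if boundary.is_empty or boundary.area == 0:
        raise ValueError("cannot compute depth of a zero-area polygon")
    if resolution is None:
        minx, miny, maxx, maxy = boundary.bounds
        resolution = float(np.hypot(maxx - minx, maxy - miny)) / 2000.0
    if resolution <= 0:
        raise ValueError(f"resolution must be > 0, got {resolution}")

    best_xy, best_d = _grid_depth(boundary, resolution)
    res = minimize(
        lambda xy: -_signed_distance(xy, boundary),
        best_xy,
        method="Nelder-Mead",
        options={"xatol": resolution * 1e-3, "fatol": resolution * 1e-6},
    )
    refined = -res.fun
    depth = max(best_d, refined)
    if not depth > 0:
        raise ValueError("region depth is not positive; degenerate geometry")
    return float(depth)


def _components(boundary: BaseGeometry) -> list[Polygon]:
    if isinstance(boundary, MultiPolygon):
        return list(boundary.geoms)
    return [boundary]


def edge_coefficients(
    region: Region, resolution: float | None = None
) -> EdgeCoefficients:
    """Edge coefficients for every SU of a region.

    Each SU receives the coefficient of its centroid: ``eps_i = 1 - 2 d_i / D``
    with ``d_i`` the centroid's distance to the boundary and ``D`` the depth of
    the component containing it.  Distances are clipped at ``D`` (a centroid
    can sit marginally deeper than the grid-estimated depth) so that
    ``eps_i`` is always in [-1, 1].
    """
    comps = _components(region.boundary)
    depths = np.array([medial_depth(c, resolution) for c in comps])
    pts = shapely.points(region.centroids)
    d = np.empty(region.n)
    comp_depth = np.empty(region.n)
    for i, (u, p) in enumerate(zip(region.units, pts)):
        for c, dc in zip(comps, depths):
            if c.covers(p):
                d[i] = shapely.distance(p, c.boundary)
                comp_depth[i] = dc
                break
        else:
            raise ValueError(f"unit {u.id!r}: centroid outside boundary")
    d = np.minimum(d, comp_depth)
    eps = 1.0 - 2.0 * d / comp_depth
    depth_out: float | np.ndarray = (
        float(depths[0]) if len(comps) == 1 else comp_depth
    )
    return EdgeCoefficients(d=d, depth=depth_out, epsilon=eps)


def edge_coefficient_field(
    boundary: BaseGeometry, n_points: int, depth: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the edge-coefficient surface on a regular interior grid.

    Returns ``(points, eps)`` with ``points`` of shape (k, 2), ``k`` close to
    ``n_points``, for export as a continuous map of the coefficient (the kind
    of rendering used to visualise the edge gradient over a whole region).
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if depth is None:
        depth = medial_depth(boundary)
    spacing = float(np.sqrt(boundary.area / n_points))
    minx, miny, maxx, maxy = boundary.bounds
    xs = np.arange(minx + spacing / 2, maxx, spacing)
    ys = np.arange(miny + spacing / 2, maxy, spacing)
    gx, gy = np.meshgrid(xs, ys)
    flat = np.column_stack([gx.ravel(), gy.ravel()])
    inside = shapely.contains_xy(boundary, flat[:, 0], flat[:, 1])
    pts = flat[inside]
    dists = shapely.distance(shapely.points(pts), boundary.boundary)
    eps = 1.0 - 2.0 * np.minimum(dists, depth) / depth
    return pts, eps
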