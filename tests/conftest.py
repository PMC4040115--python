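import numpy as np
import pytest
from shapely.geometry import Polygon, box

from scanedge import Region, SpatialUnit


def build_region(centroids, populations, boundary):
    units = [
        SpatialUnit(id=f"u{i}", centroid=tuple(c), population=float(p))
        for i, (c, p) in enumerate(zip(centroids, populations))
    ]
    return Region(units=units, boundary=boundary)


@pytest.fixture
def unit_square():
    return box(0, 0, 1, 1)


@pytest.fixture
def square4(unit_square):
    """Well-formed 2x2 region of 4 SUs on the unit square."""
    pts = [(0.25, 0.25), (0.75, 0.25), (0.25, 0.75), (0.75, 0.75)]
    return build_region(pts, [10, 10, 10, 10], unit_square)


@pytest.fixture
def l_shape():
    """Unit square minus its upper-right 0.5 x 0.5 quadrant."""
    return Polygon([(0, 0), (1, 0), (1, 0.5), (0.5, 0.5), (0.5, 1), (0, 1)])


def random_convex_polygon(rng, n_vertices=8, scale=1.0):
    """Convex hull of random points on an ellipse arc — always convex, valid."""
    theta = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    a, b = rng.uniform(0.5, 2.0, 2) * scale
    pts = np.column_stack([a * np.cos(theta), b * np.sin(theta)])
    return Polygon(pts).convex_hull
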