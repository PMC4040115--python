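"""Edge coefficients: how "on the edge" is each spatial unit?

eps_i = 1 - 2 d_i / D maps the centroid's distance to the region boundary
(d_i) onto [-1, +1] using the region depth D (the radius of the largest
inscribed circle, attained on the medial axis): +1 on the boundary, -1 at the
deepest interior point.
"""

import numpy as np
from shapely.geometry import box

from scanedge import distance_to_edge, edge_coefficients, make_auvergne_like, medial_depth

# reference geometry: the unit square
square = box(0, 0, 1, 1)
print(f"unit square depth D = {medial_depth(square):.4f}   (inscribed radius, exact 0.5)")
print(f"distance of centre to edge = {distance_to_edge((0.5, 0.5), square):.4f}")

region = make_auvergne_like(seed=1)
eps = edge_coefficients(region)
print(f"\nsynthetic region: depth D = {eps.depth:.3f} (same units as coordinates)")
print(
    f"edge coefficients span [{eps.epsilon.min():+.3f}, {eps.epsilon.max():+.3f}]: "
    "near +1 = border SUs, near -1 = deepest central SUs"
)
print(f"median |eps| = {np.median(np.abs(eps.epsilon)):.3f}")
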