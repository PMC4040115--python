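"""Build a synthetic study region and inspect its population structure.

The generator emulates a rural region tessellated into ZIP-code-like spatial
units (SUs): jittered quasi-regular centroids inside an irregular polygon,
log-normal at-risk populations (mean annual live births) whose quartile
cut-offs fall near 17 / 35 / 70.
"""

import numpy as np

from scanedge import make_auvergne_like, validate_region
from scanedge import io as sio

region = make_auvergne_like(seed=1)
q1, q2, q3 = np.percentile(region.populations, [25, 50, 75])

print(f"spatial units:        {region.n}")
print(f"total population:     {region.total_population:.0f} births/year")
print(f"population quartiles: {q1:.1f} / {q2:.1f} / {q3:.1f}  (target ~17/35/70)")
print(f"validation issues:    {validate_region(region) or 'none'}")

sio.write_region(region, "scratch_region.geojson")
print("region written to scratch_region.geojson (SU points + boundary polygon)")
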