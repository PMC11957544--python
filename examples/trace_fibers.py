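"""Trace muscle-like fibers and census their anatomical orientations.

Renders 12 fibers of the four body-wall classes (circular, diagonal,
longitudinal, dorsoventral) at SNR 5 in a 128³ volume, detects them by
orientation-swept cylinder correlation (the anterior-pole template:
length 18, outer radius 2.8, mask radius 3), traces the correlation
ridge into polylines, classifies each by its angle to the body axes,
and prints the per-class census of a physical region.
"""

import numpy as np

import planaquant as pq
from planaquant.phantoms import DEFAULT_BODY_FRAME

fibers_spec = [(c, 60.0, 2.8) for c in
               ("circular", "diagonal", "longitudinal", "dorsoventral")] * 3
grid, truth = pq.make_fiber_phantom(fibers=fibers_spec, shape=(128, 128, 128),
                                    snr=5.0, seed=11)
grid = pq.gaussian_smooth(grid, 1.0)

template = pq.CylinderTemplate(length=18, outer_radius=2.8, mask_radius=3,
                               angular_step=15)
field = pq.cylinder_correlate(grid, template)
fibers = pq.trace_correlation_lines(field, seed_threshold=0.5, min_length=30)
pq.classify_orientation(fibers, DEFAULT_BODY_FRAME)

print(f"planted fibers: {len(truth['fibers'])}, traced: {len(fibers)}")
print()
print(fibers.to_dataframe()[["id", "length_um", "class"]].to_string(index=False))

box = pq.RegionBox((0, 0, 0), (128, 128, 128), name="whole-volume")
print()
print(pq.fiber_region_stats(fibers, box).to_string(index=False))
print()
print("Counts per orientation class within the census box; proportions\n"
      "sum to 1. On real body-wall muscle data the same census run in a\n"
      "fixed-size region compares fiber-type composition across animals.")
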