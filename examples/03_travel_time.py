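"""Least-cost travel time to the nearest emergency facility.

Moving between adjacent cells costs metres x mean friction (min/m), over
an 8-connected neighbourhood; the surface is the multi-source shortest
path from all facilities.  On the tiny uniform fixture the numbers are
hand-checkable: 1 km at 0.02 min/m is 20 minutes.
"""

import numpy as np

from ambusim import (
    SyntheticSpec,
    generate_density,
    generate_friction_and_facilities,
    least_cost_travel_time,
    tiny_fixture,
)

density, friction, facilities = tiny_fixture()
tt = least_cost_travel_time(friction, facilities)
print("tiny 5x5 fixture (facility at centre, 0.02 min/m everywhere):")
print(np.round(tt.values, 2))
print("orthogonal neighbour = 20 min; diagonal = 20*sqrt(2) = 28.28 min\n")

spec = SyntheticSpec(shape=(50, 50), seed=42)
dens = generate_density(spec)
fric, facs = generate_friction_and_facilities(spec, dens)
surface = least_cost_travel_time(fric, facs)
finite = surface.values[np.isfinite(surface.values)]
print(f"synthetic 50x50 region, {len(facs)} facilities:")
print(f"  travel time: median {np.median(finite):.0f} min, max {finite.max():.0f} min")
print(f"  cells within 120 min: {np.mean(finite <= 120) * 100:.0f}%")
print("Roads act as fast corridors; remote off-road cells can be many hours away.")
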