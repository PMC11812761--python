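"""Generate a synthetic study region: density, friction and facilities.

Towns are Gaussian density bumps on a sparse rural background; roads are
low-friction corridors between town centres; emergency facilities sit in
the largest towns (mirroring the empirical pattern that density is high
near hospitals).  Everything is deterministic given the seed.
"""

from pathlib import Path

import numpy as np

from ambusim import SyntheticSpec, generate_density, generate_friction_and_facilities, write_raster

spec = SyntheticSpec(shape=(50, 50), n_towns=6, n_facilities=2, seed=42)
density = generate_density(spec)
friction, facilities = generate_friction_and_facilities(spec, density)

out = Path("scratch/example_region")
out.mkdir(parents=True, exist_ok=True)
write_raster(density, out / "density.tif")
write_raster(friction, out / "friction.tif")
facilities.to_csv(out / "facilities.csv")

print(f"density: {density.shape} cells of {spec.cell_km} km, "
      f"{density.values.min():.0f}-{density.values.max():.0f} persons/km2")
road = friction.values == spec.road_friction_min_per_m
print(f"friction: {int(road.sum())} road cells at {spec.road_friction_min_per_m} min/m, "
      f"off-road {spec.offroad_friction_min_per_m} min/m")
print("facilities:", ", ".join(f"{n} at {c}" for n, c in zip(facilities.names, facilities.coords)))
print(f"total population: {density.values.sum() * density.cell_area_km2:,.0f}")
print(f"written to {out}/")
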