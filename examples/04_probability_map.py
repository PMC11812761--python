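"""Map the probability that the ambulance improves transfer time.

q(x) = Pr[tau(x) > (2s-1) t(x)] is high where the waiting delay is long
(sparse areas) and the facility is near, and low in dense areas where
informal transport is found quickly.  This is the map a planner would use
to target the service.
"""

import numpy as np

from ambusim import (
    DelayParams,
    SpeedParams,
    SyntheticSpec,
    generate_density,
    generate_friction_and_facilities,
    least_cost_travel_time,
    q_map,
)

spec = SyntheticSpec(shape=(50, 50), seed=42)
density = generate_density(spec)
friction, facilities = generate_friction_and_facilities(spec, density)
tt = least_cost_travel_time(friction, facilities)

for beta, s in [(60, 0.9), (300, 0.9), (300, 0.6)]:
    qm = q_map(tt, density, DelayParams(beta), SpeedParams(s))
    vals = qm.values[~np.isnan(qm.values)]
    print(f"beta={beta:3d} s={s:.1f}: median q = {np.median(vals):.3f}, "
          f"share of cells with q > 0.5: {np.mean(vals > 0.5) * 100:.0f}%")

print("\nLonger waiting delays (large beta) and faster ambulances (small s)")
print("both raise the share of the region where the ambulance wins.")
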