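"""Waiting delays for informal transport and when the ambulance wins.

The waiting delay tau is the time spent finding a vehicle and driver for
informal transport; it is Rayleigh with mean beta/sqrt(rho).  At the
reference density of 137 persons/km2 the mean delay runs from ~5 minutes
(beta=60) to ~26 minutes (beta=300).  The probability q that a
facility-based ambulance (round trip 2*s*t) beats informal transport is
the Rayleigh survival function at the threshold (2s-1)*t.
"""

from ambusim import DelayParams, SpeedParams, expected_delay, prob_ambulance_faster

RHO = 137.0  # persons/km2

print("mean waiting delay at", RHO, "persons/km2:")
for beta in (60, 120, 180, 240, 300):
    print(f"  beta={beta:3d}: {expected_delay(beta, RHO):5.1f} min")

print("\nprobability the ambulance is faster (t = 20 min one-way):")
for s in (0.5, 0.6, 0.9):
    for beta in (60, 300):
        q = prob_ambulance_faster(20.0, RHO, DelayParams(beta), SpeedParams(s))
        print(f"  s={s:.1f} beta={beta:3d}: q = {q:.4f}")
print("\nAt s=0.5 the round trip never loses (q=1); a nearly ordinary-speed")
print("ambulance (s=0.9) in a dense area almost never beats informal transport.")
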