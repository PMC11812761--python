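"""Transfer-time rules and per-cell survival with and without the ambulance.

Without an ambulance a patient travels informally: t0 = t + τ (one-way
travel time plus the waiting delay).  With a facility-based ambulance hub
the round trip takes t_amb = 2·s·t (+ an optional call-out delay θ,
default 0).  Three choice rules govern the with-ambulance time t1:

* ``fastest``   — patients take whichever is quicker: t1 = min(t + τ, 2st);
* ``ambulance`` — patients always take the ambulance: t1 = 2st;
* ``random``    — a fraction w takes the ambulance; survival is the
  w-mixture, exact in expectation for cells carrying expected case counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ambusim.delay import SpeedParams
from ambusim.survival import survival_prob

CHOICE_RULES = ("fastest", "ambulance", "random")


@dataclass
class ScenarioSpec:
    choice_rule: str = "fastest"
    random_weight: float = 0.5
    callout_delay: float = 0.0  # θ, minutes; beyond the base model, default off

    def __post_init__(self) -> None:
        if self.choice_rule not in CHOICE_RULES:
            raise ValueError(f"unknown choice rule {self.choice_rule!r}; choose from {CHOICE_RULES}")
        if not (0.0 <= self.random_weight <= 1.0):
            raise ValueError("random_weight must lie in [0, 1]")
        if self.callout_delay < 0:
            raise ValueError("callout_delay must be non-negative")


def t_ambulance(t, speed: SpeedParams, callout_delay: float = 0.0):
    """Round-trip ambulance time from a facility-based hub: 2·s·t (+ θ)."""
    return 2.0 * speed.s * np.asarray(t, dtype=float) + callout_delay


def t_informal(t, tau):
    """Informal transport time: one-way travel time plus waiting delay."""
    return np.asarray(t, dtype=float) + np.asarray(tau, dtype=float)


def cell_survival_pair(t, tau, speed: SpeedParams, lam: float,
                       spec: ScenarioSpec):
    """(S0, S1): survival without and with the ambulance service.

    Vectorised over ``t`` and ``tau``.  Infinite travel times propagate to
    survival 0 under both scenarios.
    """
    t0 = t_informal(t, tau)
    ta = t_ambulance(t, speed, spec.callout_delay)
    s0 = survival_prob(lam, t0)
    if spec.choice_rule == "fastest":
        s1 = survival_prob(lam, np.minimum(t0, ta))
    elif spec.choice_rule == "ambulance":
        s1 = survival_prob(lam, ta)
    else:  # random: expectation over the w : (1-w) split
        w = spec.random_weight
        s1 = w * survival_prob(lam, ta) + (1.0 - w) * s0
    return s0, s1
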