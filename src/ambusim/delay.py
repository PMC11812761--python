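"""The Rayleigh waiting-delay model and the probability of improved transfer.

When no ambulance exists, a patient must locate a vehicle and driver for
informal transport.  That "waiting delay" τ(x) is modelled as Rayleigh with
mean β/√ρ(x): β is the mean waiting delay (minutes) where the population
density is one person per km², and the delay shrinks as the square root of
local density — the nearest-available-vehicle distance in a Poisson field
of vehicles scales as ρ^(−1/2).

The probability that the ambulance beats informal transport at a cell with
one-way travel time t is

    q(x) = Pr[τ(x) > (2s − 1) t(x)],

where s ∈ (0, 1] is the ambulance speed multiplier and the factor 2s
reflects the facility-based hub's round trip.  For s ≤ 0.5 the round trip
never exceeds the informal one-way time, so q = 1 everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ambusim.raster import RasterGrid, assert_aligned

_SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)


@dataclass
class DelayParams:
    """β: mean waiting delay in minutes at density 1 person/km²."""

    beta: float

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")


@dataclass
class SpeedParams:
    """s: ambulance travel time as a fraction of standard-vehicle time."""

    s: float

    def __post_init__(self) -> None:
        if not (0.0 < self.s <= 1.0):
            raise ValueError("speed multiplier s must lie in (0, 1]")


def expected_delay(beta: float, rho) -> float | np.ndarray:
    """Mean waiting delay in minutes at density ``rho`` (persons/km²): β/√ρ."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("density must be positive (zero-density cells are excluded upstream)")
    out = beta / np.sqrt(rho)
    return float(out) if out.ndim == 0 else out


def rayleigh_scale(beta: float, rho) -> float | np.ndarray:
    """Rayleigh scale σ with mean β/√ρ: σ = (β/√ρ)·√(2/π)."""
    out = np.asarray(expected_delay(beta, rho)) * _SQRT_2_OVER_PI
    return float(out) if out.ndim == 0 else out


def sample_delay(beta: float, rho, rng: np.random.Generator, size=None):
    """Rayleigh(σ(β, ρ)) draws in minutes; always ≥ 0.

    ``rho`` may be an array, in which case one draw is made per element
    (``size`` must then be None or broadcast-compatible).
    """
    sigma = np.asarray(rayleigh_scale(beta, rho))
    if size is None and sigma.ndim > 0:
        size = sigma.shape
    # unit-scale draws times sigma: with common random numbers, draws scale
    # linearly in beta, which the monotonicity checks on results grids rely on
    return rng.rayleigh(scale=1.0, size=size) * sigma


def prob_ambulance_faster(t, rho, delay: DelayParams, speed: SpeedParams):
    """q = Pr[τ > (2s−1)·t], the Rayleigh survival function at the threshold.

    Unreachable cells (t = +inf) get q = 0: neither mode can deliver the
    patient, so no improvement is possible.  Scalars in, scalar out.
    """
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0 and np.ndim(rho) == 0
    t_arr = np.atleast_1d(t_arr)
    if np.any(t_arr[np.isfinite(t_arr)] < 0):
        raise ValueError("travel time must be non-negative")
    sigma = np.atleast_1d(np.asarray(rayleigh_scale(delay.beta, rho)))
    sigma, t_arr = np.broadcast_arrays(sigma, t_arr)

    threshold = (2.0 * speed.s - 1.0) * t_arr
    with np.errstate(over="ignore", invalid="ignore"):
        q = np.where(np.isfinite(t_arr),
                     np.where(threshold <= 0.0, 1.0,
                              np.exp(-np.square(threshold) / (2.0 * np.square(sigma)))),
                     0.0)
    return float(q[0]) if scalar else q.reshape(np.broadcast_shapes(np.shape(t), np.shape(rho)) or (1,))


def q_map(t_surface: RasterGrid, density: RasterGrid, delay: DelayParams,
          speed: SpeedParams) -> RasterGrid:
    """Per-cell probability of improved transfer time with the ambulance.

    Cells with nodata or zero density carry no population and are set to
    nodata (NaN) in the output.
    """
    assert_aligned([t_surface, density], names=["travel_time", "density"])
    rho = np.asarray(density.values, dtype=float)
    populated = density.valid_mask() & (rho > 0)
    out = np.full(density.shape, np.nan)
    if populated.any():
        out[populated] = prob_ambulance_faster(
            np.asarray(t_surface.values, dtype=float)[populated],
            rho[populated], delay, speed)
    grid = density.copy_with(out, units="probability")
    grid.nodata = float("nan")
    return grid
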