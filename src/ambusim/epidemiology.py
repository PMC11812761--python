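"""Incidence of the marker condition and expected cases per cell.

Incidence is drawn from a Gamma distribution whose draws are read as a
percentage of live births (the default Gamma(shape 2, scale 0.5) has mode
0.5, i.e. the most likely incidence is 0.5% of live births).  Live births
per cell come from the population density times a crude birth rate.
Care-seeking proportions p0 (without the ambulance) and p1 (with it) allow
supply-induced demand; both default to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ambusim.raster import RasterGrid


@dataclass
class IncidenceParams:
    gamma_shape: float = 2.0
    gamma_scale: float = 0.5  # draws are percent of live births
    birth_rate_per_1000: float = 27.5
    p0: float = 1.0
    p1: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma_shape <= 1:
            raise ValueError("gamma_shape must exceed 1 so the mode is positive")
        if self.gamma_scale <= 0:
            raise ValueError("gamma_scale must be positive")
        if self.birth_rate_per_1000 < 0:
            raise ValueError("birth rate must be non-negative")
        for name in ("p0", "p1"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def mean_incidence_fraction(self) -> float:
        """Gamma mean (shape·scale, percent) as a fraction of live births."""
        return self.gamma_shape * self.gamma_scale / 100.0


def incidence_mode(params: IncidenceParams) -> float:
    """Mode of the incidence distribution in percent: (shape − 1)·scale."""
    return (params.gamma_shape - 1.0) * params.gamma_scale


def sample_incidence(params: IncidenceParams, rng: np.random.Generator) -> float:
    """One Gamma(shape, scale) draw, converted percent → fraction of live births."""
    return float(rng.gamma(params.gamma_shape, params.gamma_scale)) / 100.0


def cases_per_cell(density: RasterGrid, incidence_fraction: float,
                   params: IncidenceParams) -> RasterGrid:
    """Expected annual severe cases per cell.

    cases = ρ · cell_area_km² · (birth rate / 1000) · incidence_fraction.
    Fractional expected counts are used directly, matching the integral
    formulation of the lives-saved estimator; nodata density cells give 0.
    """
    if incidence_fraction < 0:
        raise ValueError("incidence_fraction must be non-negative")
    rho = np.asarray(density.values, dtype=float)
    cases = np.where(density.valid_mask(), rho, 0.0) * density.cell_area_km2 \
        * (params.birth_rate_per_1000 / 1000.0) * incidence_fraction
    return density.copy_with(cases, units="cases/year")
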