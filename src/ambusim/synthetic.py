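"""Synthetic density / friction / facility generators.

Real inputs to the model are a population-density raster (WorldPop-style,
persons per km²) and a friction surface (minutes per metre, Weiss-style)
plus emergency-facility coordinates.  This module emits aligned synthetic
versions of all three with controllable spatial structure — clustered
"towns" of high density on a sparse background, and low-friction road
corridors linking town centres across high-friction terrain — so the whole
pipeline runs and is testable without any download.

Everything is deterministic given ``SyntheticSpec.seed`` (NumPy PCG64
streams): towns are drawn first, then roads, then facilities, each from its
own child stream so any artefact is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import line as _raster_line

from ambusim.raster import RasterGrid
from ambusim.travel import FacilitySet


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic region.

    Defaults give a 50×50 grid of 1 km cells with a handful of towns whose
    peak densities are of the order of a densely settled district town, a
    low rural background, and roads an order of magnitude faster than
    off-road terrain (0.0012 min/m ≈ 50 km/h vs 0.03 min/m ≈ 2 km/h
    walking pace).
    """

    shape: tuple[int, int] = (50, 50)
    cell_km: float = 1.0
    n_towns: int = 6
    town_peak_density: float = 2000.0
    background_density: float = 5.0
    town_sd_km: float = 3.0
    n_roads: int = 8
    road_friction_min_per_m: float = 0.0012
    offroad_friction_min_per_m: float = 0.03
    n_facilities: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.road_friction_min_per_m >= self.offroad_friction_min_per_m:
            raise ValueError("road friction must be lower than off-road friction")
        if self.town_peak_density <= 0 or self.background_density < 0:
            raise ValueError("densities must be positive (peak) / non-negative (background)")
        if self.town_sd_km <= 0 or self.cell_km <= 0:
            raise ValueError("town_sd_km and cell_km must be positive")
        if self.n_towns < 0 or self.n_roads < 0:
            raise ValueError("counts must be non-negative")
        if self.n_facilities < 1:
            raise ValueError("need at least one facility")
        if self.n_facilities > max(self.n_towns, 1):
            raise ValueError("n_facilities cannot exceed n_towns")


def _streams(spec: SyntheticSpec):
    towns, roads, facilities = np.random.SeedSequence(spec.seed).spawn(3)
    return (np.random.default_rng(towns), np.random.default_rng(roads),
            np.random.default_rng(facilities))


def _transform(spec: SyntheticSpec):
    # north-up grid in a metre-based planar frame with origin at top-left
    m = spec.cell_km * 1000.0
    nrows = spec.shape[0]
    return (m, 0.0, 0.0, 0.0, -m, nrows * m)


def _town_layout(spec: SyntheticSpec):
    """Town centre cells and amplitudes, deterministic given the seed.

    Amplitudes are U(0.5, 1)·peak so that ranking towns by size (for
    facility placement) is well defined while the maximum stays below the
    nominal peak.
    """
    rng, _, _ = _streams(spec)
    nrows, ncols = spec.shape
    centres = np.column_stack([
        rng.integers(0, nrows, size=spec.n_towns),
        rng.integers(0, ncols, size=spec.n_towns),
    ]) if spec.n_towns else np.empty((0, 2), dtype=int)
    amps = spec.town_peak_density * rng.uniform(0.5, 1.0, size=spec.n_towns)
    return centres, amps


def generate_density(spec: SyntheticSpec) -> RasterGrid:
    """Background density plus Gaussian town kernels.

    Each town contributes ``amp · exp(−r²/(2·sd²))`` with r the distance in
    km from its centre cell, truncated at 4 sd (negligible mass beyond).
    """
    nrows, ncols = spec.shape
    values = np.full(spec.shape, spec.background_density, dtype=float)
    centres, amps = _town_layout(spec)

    rows = np.arange(nrows)[:, None]
    cols = np.arange(ncols)[None, :]
    sd_cells = spec.town_sd_km / spec.cell_km
    for (r0, c0), amp in zip(centres, amps):
        r2 = (rows - r0) ** 2 + (cols - c0) ** 2
        kernel = np.where(r2 <= (4.0 * sd_cells) ** 2,
                          amp * np.exp(-r2 / (2.0 * sd_cells**2)), 0.0)
        values += kernel

    return RasterGrid(values=values, transform=_transform(spec),
                      cell_width_km=spec.cell_km, cell_height_km=spec.cell_km,
                      units="persons/km2")


def generate_friction_and_facilities(spec: SyntheticSpec,
                                     density: RasterGrid) -> tuple[RasterGrid, FacilitySet]:
    """Friction raster with road corridors, plus facilities at the largest towns.

    Roads are straight rasterised segments between randomly paired town
    centres; the first segments chain the facility towns together so every
    facility lies on the road network.  With no towns, a single facility is
    placed at the grid centre.
    """
    _, road_rng, _ = _streams(spec)
    centres, amps = _town_layout(spec)
    values = np.full(spec.shape, spec.offroad_friction_min_per_m, dtype=float)

    if spec.n_towns == 0:
        fac_cells = [(spec.shape[0] // 2, spec.shape[1] // 2)]
    else:
        order = np.argsort(amps)[::-1]
        fac_cells = [tuple(centres[i]) for i in order[: spec.n_facilities]]

    segments: list[tuple[tuple[int, int], tuple[int, int]]] = []
    if spec.n_towns >= 2:
        # chain the facility towns first, then random town pairs
        ranked = [tuple(centres[i]) for i in np.argsort(amps)[::-1]]
        for a, b in zip(ranked[: spec.n_facilities], ranked[1: spec.n_facilities + 1]):
            segments.append((a, b))
        while len(segments) < spec.n_roads:
            i, j = road_rng.choice(spec.n_towns, size=2, replace=False)
            segments.append((tuple(centres[i]), tuple(centres[j])))
        segments = segments[: max(spec.n_roads, spec.n_facilities - 1)]

    for (r0, c0), (r1, c1) in segments:
        rr, cc = _raster_line(int(r0), int(c0), int(r1), int(c1))
        values[rr, cc] = spec.road_friction_min_per_m

    # town centres (hence facilities) always sit on the network
    for r0, c0 in fac_cells:
        values[r0, c0] = spec.road_friction_min_per_m

    friction = density.copy_with(values, units="min/m")
    xs, ys = [], []
    for r0, c0 in fac_cells:
        x, y = friction.xy(int(r0), int(c0))
        xs.append(x)
        ys.append(y)
    facilities = FacilitySet(
        names=[f"facility_{i}" for i in range(len(fac_cells))],
        coords=list(zip(xs, ys)),
    )
    return friction, facilities


def tiny_fixture() -> tuple[RasterGrid, RasterGrid, FacilitySet]:
    """Hand-checkable 5×5 region: uniform friction 0.02 min/m, density 100
    persons/km² everywhere, one facility at the centre cell, 1 km cells.

    Travel times from the centre are then ``0.02 × path length in metres``:
    20 min to an orthogonal neighbour, 20·√2 ≈ 28.28 min to a diagonal one.
    """
    transform = (1000.0, 0.0, 0.0, 0.0, -1000.0, 5000.0)
    density = RasterGrid(np.full((5, 5), 100.0), transform, 1.0, 1.0, units="persons/km2")
    friction = RasterGrid(np.full((5, 5), 0.02), transform, 1.0, 1.0, units="min/m")
    x, y = friction.xy(2, 2)
    return density, friction, FacilitySet(names=["central"], coords=[(x, y)])
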