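"""Least-cost travel time t(x) to the nearest emergency-capable facility.

Travel time is computed as a multi-source shortest path over the friction
raster: moving between adjacent cells i → j costs ``d(i, j) metres ×
edge_friction(i, j) min/m`` with an 8-connected neighbourhood (orthogonal
step = cell size, diagonal = cell size × √2; optional 16-connectivity adds
knight's moves at √5).  The friction combining rule for an edge defaults to
the arithmetic mean of the two cells, with ``min`` and ``max`` variants
exposed because cost-distance dialects differ on this point.

All facility cells are sources at time zero and the surface holds the
minimum over facilities; nodata friction cells are impassable and
unreachable cells get +inf.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from ambusim.raster import RasterGrid

logger = logging.getLogger(__name__)

_OFFSETS_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_OFFSETS_KNIGHT = [(-2, -1), (-2, 1), (-1, -2), (-1, 2), (1, -2), (1, 2), (2, -1), (2, 1)]

_EDGE_RULES = {
    "mean": lambda a, b: 0.5 * (a + b),
    "min": np.minimum,
    "max": np.maximum,
}


@dataclass
class FacilitySet:
    """Named emergency-capable facility locations.

    ``coords`` are projected/geographic (x, y) pairs in the raster's frame;
    they are snapped to the nearest cell centre before path computation.
    """

    names: list[str]
    coords: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.coords):
            raise ValueError("names and coords must have equal length")
        if len(self.coords) == 0:
            raise ValueError("facility set is empty")

    def __len__(self) -> int:
        return len(self.coords)

    def snap(self, grid: RasterGrid) -> np.ndarray:
        """(row, col) of each facility on ``grid``; errors if outside or on nodata."""
        cells = []
        valid = grid.valid_mask()
        nrows, ncols = grid.shape
        for name, (x, y) in zip(self.names, self.coords):
            row, col = grid.index(x, y)
            if not (0 <= row < nrows and 0 <= col < ncols):
                raise ValueError(f"facility {name!r} at ({x}, {y}) lies outside the raster")
            if not valid[row, col]:
                raise ValueError(f"facility {name!r} snaps to a nodata/impassable cell ({row}, {col})")
            cells.append((row, col))
        return np.array(cells, dtype=int)

    @classmethod
    def from_csv(cls, path) -> "FacilitySet":
        """Read a facility table with header ``name,lon,lat``."""
        df = pd.read_csv(path)
        missing = {"name", "lon", "lat"} - set(df.columns)
        if missing:
            raise ValueError(f"facility CSV missing columns: {sorted(missing)}")
        return cls(names=df["name"].astype(str).tolist(),
                   coords=list(zip(df["lon"].astype(float), df["lat"].astype(float))))

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "name": self.names,
            "lon": [x for x, _ in self.coords],
            "lat": [y for _, y in self.coords],
        }).to_csv(path, index=False)


def _offsets(connectivity: int):
    if connectivity == 8:
        return _OFFSETS_8
    if connectivity == 16:
        return _OFFSETS_8 + _OFFSETS_KNIGHT
    raise ValueError("connectivity must be 8 or 16")


def least_cost_travel_time(friction: RasterGrid, facilities: FacilitySet,
                           edge_cost: str = "mean",
                           connectivity: int = 8) -> RasterGrid:
    """Multi-source Dijkstra travel-time surface in minutes.

    Parameters
    ----------
    friction:
        Raster in min/m; nodata cells are impassable.
    facilities:
        Source locations, snapped to cell centres.
    edge_cost:
        How the two cells' frictions combine on an edge: ``"mean"``
        (default), ``"min"`` or ``"max"``.
    connectivity:
        8 (default) or 16 (adds knight's moves).
    """
    if edge_cost not in _EDGE_RULES:
        raise ValueError(f"unknown edge_cost {edge_cost!r}; choose from {sorted(_EDGE_RULES)}")
    combine = _EDGE_RULES[edge_cost]
    fric = np.asarray(friction.values, dtype=float)
    valid = friction.valid_mask() & np.isfinite(fric)
    if np.any(fric[valid] <= 0):
        raise ValueError("friction values must be positive")
    nrows, ncols = friction.shape
    n = nrows * ncols
    w_m = friction.cell_width_km * 1000.0
    h_m = friction.cell_height_km * 1000.0

    rows_idx, cols_idx, costs = [], [], []
    for dr, dc in _offsets(connectivity):
        # pair every cell with its (dr, dc) neighbour where both are passable
        src = valid[max(0, -dr): nrows - max(0, dr), max(0, -dc): ncols - max(0, dc)]
        dst = valid[max(0, dr): nrows + min(0, dr), max(0, dc): ncols + min(0, dc)]
        both = src & dst
        if not both.any():
            continue
        r, c = np.nonzero(both)
        r = r + max(0, -dr)
        c = c + max(0, -dc)
        i = r * ncols + c
        j = (r + dr) * ncols + (c + dc)
        dist_m = float(np.hypot(dr * h_m, dc * w_m))
        costs.append(dist_m * combine(fric[r, c], fric[r + dr, c + dc]))
        rows_idx.append(i)
        cols_idx.append(j)

    sources_rc = facilities.snap(friction)
    sources = sources_rc[:, 0] * ncols + sources_rc[:, 1]

    if rows_idx:
        graph = coo_matrix(
            (np.concatenate(costs), (np.concatenate(rows_idx), np.concatenate(cols_idx))),
            shape=(n, n),
        ).tocsr()
        times = dijkstra(graph, directed=False, indices=sources, min_only=True)
    else:
        times = np.full(n, np.inf)
        times[sources] = 0.0

    surface = times.reshape(nrows, ncols)
    surface[~valid] = np.inf
    n_unreachable = int(np.isinf(surface[valid]).sum())
    if n_unreachable:
        logger.warning("%d passable cells are unreachable from any facility", n_unreachable)
    return friction.copy_with(surface, units="minutes")


def brute_force_travel_time(friction: RasterGrid, facilities: FacilitySet,
                            edge_cost: str = "mean",
                            connectivity: int = 8) -> RasterGrid:
    """Exact travel times on tiny grids by exhaustive edge relaxation.

    A pure-Python Bellman–Ford sweep over the explicit edge list, repeated
    until no label improves — exact for non-negative costs and wholly
    independent of the Dijkstra implementation.  Test oracle only; refuses
    grids larger than 5×5.
    """
    nrows, ncols = friction.shape
    if nrows > 5 or ncols > 5:
        raise ValueError("brute-force oracle only supports grids up to 5x5")
    combine = _EDGE_RULES[edge_cost]
    fric = friction.values
    valid = friction.valid_mask() & np.isfinite(np.asarray(fric, dtype=float))
    w_m = friction.cell_width_km * 1000.0
    h_m = friction.cell_height_km * 1000.0

    edges = []
    for r in range(nrows):
        for c in range(ncols):
            if not valid[r, c]:
                continue
            for dr, dc in _offsets(connectivity):
                rr, cc = r + dr, c + dc
                if 0 <= rr < nrows and 0 <= cc < ncols and valid[rr, cc]:
                    dist_m = (dr * h_m) ** 2 + (dc * w_m) ** 2
                    cost = dist_m ** 0.5 * float(combine(fric[r, c], fric[rr, cc]))
                    edges.append(((r, c), (rr, cc), cost))

    label = {(r, c): float("inf") for r in range(nrows) for c in range(ncols)}
    for r, c in facilities.snap(friction):
        label[(int(r), int(c))] = 0.0
    changed = True
    while changed:
        changed = False
        for u, v, cost in edges:
            if label[u] + cost < label[v] - 1e-15:
                label[v] = label[u] + cost
                changed = True

    out = np.full((nrows, ncols), np.inf)
    for (r, c), t in label.items():
        out[r, c] = t
    out[~valid] = np.inf
    return friction.copy_with(out, units="minutes")
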