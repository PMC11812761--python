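"""Georeferenced single-band rasters: the common container for density,
friction, travel-time, probability and lives-saved surfaces.

GeoTIFF I/O is implemented on :mod:`tifffile` using the standard GeoTIFF
georeferencing tags (ModelPixelScale, ModelTiepoint, GDAL_NODATA).  The
transform is the usual six-coefficient affine map in rasterio order::

    x = a*col + b*row + c
    y = d*col + e*row + f

with a north-up convention (row 0 is the top row, ``e`` negative) and cell
values referring to cell centres.  No reprojection is performed; all rasters
entering one model run must already share a grid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

# GeoTIFF / GDAL tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

#: recognised unit tags for the surfaces the model passes around
UNIT_TAGS = ("persons/km2", "min/m", "minutes", "probability", "lives", "cases/year")


class RasterFormatError(ValueError):
    """Raised for unreadable or structurally invalid raster files."""


class AlignmentError(ValueError):
    """Raised when rasters that must share a grid do not."""


@dataclass
class RasterGrid:
    """A single-band georeferenced raster.

    Parameters
    ----------
    values:
        2-D float array.  ``nodata`` cells carry the sentinel value
        (NaN by default).
    transform:
        Affine coefficients ``(a, b, c, d, e, f)`` mapping (col, row) to
        projected coordinates; see module docstring.
    cell_width_km, cell_height_km:
        Cell size in km used for the equal-area approximation in all
        integrals.  Inferred from the transform (assuming metre units) on
        read, overridable for geographic-CRS inputs.
    nodata:
        Sentinel value; NaN recommended.
    units:
        Free-text unit tag, e.g. ``"persons/km2"`` or ``"minutes"``.
    """

    values: np.ndarray
    transform: tuple[float, float, float, float, float, float]
    cell_width_km: float
    cell_height_km: float
    nodata: float = float("nan")
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=self.values.dtype
                                 if np.issubdtype(np.asarray(self.values).dtype, np.floating)
                                 else np.float64)
        if self.values.ndim != 2:
            raise RasterFormatError(f"expected a 2-D array, got ndim={self.values.ndim}")
        if not (self.cell_width_km > 0 and self.cell_height_km > 0):
            raise ValueError("cell sizes must be positive")
        self.transform = tuple(float(v) for v in self.transform)  # type: ignore[assignment]

    # -- derived geometry ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area_km2(self) -> float:
        return self.cell_width_km * self.cell_height_km

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells that are not nodata."""
        if math.isnan(self.nodata):
            return ~np.isnan(self.values)
        return self.values != self.nodata

    # -- coordinate mapping -------------------------------------------------

    def xy(self, row: int, col: int) -> tuple[float, float]:
        """Projected coordinates of the centre of cell (row, col)."""
        a, b, c, d, e, f = self.transform
        cc, rr = col + 0.5, row + 0.5
        return a * cc + b * rr + c, d * cc + e * rr + f

    def index(self, x: float, y: float) -> tuple[int, int]:
        """Cell (row, col) containing projected point (x, y).

        Only rectilinear (b = d = 0) transforms are supported, which covers
        every north-up raster this package reads or writes.
        """
        a, b, c, d, e, f = self.transform
        if b != 0 or d != 0:
            raise NotImplementedError("rotated transforms are not supported")
        col = int(math.floor((x - c) / a))
        row = int(math.floor((y - f) / e))
        return row, col

    def copy_with(self, values: np.ndarray, units: str | None = None) -> "RasterGrid":
        """New grid sharing this grid's geometry."""
        return RasterGrid(
            values=np.asarray(values, dtype=float),
            transform=self.transform,
            cell_width_km=self.cell_width_km,
            cell_height_km=self.cell_height_km,
            nodata=self.nodata,
            units=self.units if units is None else units,
        )


def read_raster(path, expected_units: str = "", cell_width_km: float | None = None,
                cell_height_km: float | None = None) -> RasterGrid:
    """Read a single-band GeoTIFF.

    Cell sizes in km are inferred from the pixel-scale tag assuming the CRS
    unit is metres; pass ``cell_width_km``/``cell_height_km`` to override
    (e.g. for degree-based rasters).

    Raises
    ------
    OSError
        If the file cannot be read.
    RasterFormatError
        If the file is multi-band or lacks georeferencing tags.
    """
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise RasterFormatError(f"{path}: expected a single-band GeoTIFF, found {len(tif.pages)} pages")
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise RasterFormatError(f"{path}: expected 1 sample per pixel, found {page.samplesperpixel}")
        values = page.asarray()
        tags = page.tags
        try:
            sx, sy, _ = tags[_TAG_MODEL_PIXEL_SCALE].value[:3]
            tie = tags[_TAG_MODEL_TIEPOINT].value
        except KeyError as exc:
            raise RasterFormatError(f"{path}: missing GeoTIFF georeferencing tags") from exc
        # tiepoint (i, j, k, x, y, z): raster point -> model point
        i, j, _k, x0, y0, _z = tie[:6]
        transform = (float(sx), 0.0, float(x0 - i * sx), 0.0, -float(sy), float(y0 + j * sy))
        nodata = float("nan")
        if _TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value))

    grid = RasterGrid(
        values=np.asarray(values),
        transform=transform,
        cell_width_km=cell_width_km if cell_width_km is not None else sx / 1000.0,
        cell_height_km=cell_height_km if cell_height_km is not None else sy / 1000.0,
        nodata=nodata,
        units=expected_units,
    )
    valid = grid.valid_mask()
    if valid.any():
        logger.info(
            "read %s: shape=%s valid=%d min=%.6g max=%.6g",
            path, grid.shape, int(valid.sum()),
            float(np.min(grid.values[valid])), float(np.max(grid.values[valid])),
        )
    else:
        logger.warning("read %s: no valid cells", path)
    return grid


def write_raster(grid: RasterGrid, path) -> None:
    """Write a grid as a single-band GeoTIFF; values round-trip bit-exactly."""
    a, b, c, d, e, f = grid.transform
    if b != 0 or d != 0:
        raise NotImplementedError("rotated transforms are not supported")
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (a, -e, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, c, f, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, _format_nodata(grid.nodata)),
    ]
    tifffile.imwrite(path, grid.values, extratags=extratags,
                     photometric="minisblack")


def _format_nodata(nodata: float) -> str:
    return "nan" if math.isnan(nodata) else repr(float(nodata))


def assert_aligned(grids: list[RasterGrid], names: list[str] | None = None,
                   tol: float = 1e-9) -> None:
    """Check that all grids share shape, transform and cell size.

    Raises :class:`AlignmentError` naming the first offending grid.
    """
    if len(grids) < 2:
        raise ValueError("need at least two grids to compare")
    if names is None:
        names = [f"grid[{i}]" for i in range(len(grids))]
    ref = grids[0]
    for name, g in zip(names[1:], grids[1:]):
        if g.shape != ref.shape:
            raise AlignmentError(f"{name}: shape {g.shape} != {ref.shape}")
        if any(abs(x - y) > tol for x, y in zip(g.transform, ref.transform)):
            raise AlignmentError(f"{name}: transform {g.transform} != {ref.transform}")
        if abs(g.cell_width_km - ref.cell_width_km) > tol or abs(g.cell_height_km - ref.cell_height_km) > tol:
            raise AlignmentError(f"{name}: cell size differs from {names[0]}")
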