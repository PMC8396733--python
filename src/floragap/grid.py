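"""Regular-grid raster container and point-to-cell assignment.

The analysis runs on an equal-area grid (10x10 km cells by default).  A
:class:`GridRaster` stores one value per cell together with explicit
geo-referencing metadata: the projected coordinate of the lower-left corner,
the cell size in metres, and a CRS identifier string.  Cells are half-open
intervals ``[edge, edge + cell_size)`` in both axes, with row 0 at the
*bottom* of the grid (lower-left origin); the ESRI ASCII-grid reader/writer
flips row order accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Sentinel cell index for points outside the raster extent.
OUTSIDE = -1


@dataclass
class GridRaster:
    """A categorical or continuous surface on a regular grid.

    Parameters
    ----------
    values : ndarray, shape (n_rows, n_cols)
        Cell values; row 0 is the southernmost row.
    origin : (float, float)
        Projected (x, y) of the lower-left corner of the grid, in metres.
    cell_size : float
        Cell edge length in metres; cells are square.
    crs : str
        Free-form CRS identifier (e.g. ``"synthetic-lcc"`` or ``"EPSG:4326"``).
    nodata : float
        Value standing for missing cells on disk; in memory missing continuous
        cells are NaN and missing categorical cells carry a sentinel id.
    """

    values: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    cell_size: float = 10_000.0
    crs: str = "synthetic-lcc"
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def n_cells(self) -> int:
        return self.values.size

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full extent."""
        x0, y0 = self.origin
        return (x0, y0, x0 + self.n_cols * self.cell_size, y0 + self.n_rows * self.cell_size)

    def same_grid(self, other: "GridRaster") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.origin[0], other.origin[0])
            and np.isclose(self.origin[1], other.origin[1])
            and np.isclose(self.cell_size, other.cell_size)
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Projected (x, y) coordinates of every cell center, each shaped like ``values``."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = y0 + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def copy(self) -> "GridRaster":
        return GridRaster(self.values.copy(), self.origin, self.cell_size, self.crs, self.nodata)

    # --- flat-index helpers -------------------------------------------------

    def flat(self) -> np.ndarray:
        """Values in flat C order with row 0 first (south to north)."""
        return self.values.reshape(-1)

    def rowcol_to_index(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        return row * self.n_cols + col


def require_same_grid(*rasters: GridRaster) -> None:
    first = rasters[0]
    for r in rasters[1:]:
        if not first.same_grid(r):
            raise ValueError("rasters are not on the same grid (shape/origin/cell_size mismatch)")


def assign_cells(x: np.ndarray, y: np.ndarray, grid: GridRaster) -> np.ndarray:
    """Assign projected points to grid cells.

    Cells are half-open: a point exactly on a shared edge belongs to the
    higher-index cell.  Points outside the extent get :data:`OUTSIDE`.

    Returns
    -------
    ndarray of int
        Flat cell index ``row * n_cols + col`` per point, or ``OUTSIDE``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x0, y0 = grid.origin
    col = np.floor((x - x0) / grid.cell_size).astype(int)
    row = np.floor((y - y0) / grid.cell_size).astype(int)
    inside = (col >= 0) & (col < grid.n_cols) & (row >= 0) & (row < grid.n_rows)
    idx = np.where(inside, row * grid.n_cols + np.clip(col, 0, grid.n_cols - 1), OUTSIDE)
    return idx


# --- ESRI ASCII grid I/O ----------------------------------------------------


def write_ascii_grid(raster: GridRaster, path: str | Path) -> None:
    """Write an ESRI ASCII grid (.asc); NaN cells become the nodata value."""
    vals = np.asarray(raster.values, dtype=float)
    out = np.where(np.isnan(vals), raster.nodata, vals)
    header = (
        f"ncols {raster.n_cols}\n"
        f"nrows {raster.n_rows}\n"
        f"xllcorner {raster.origin[0]:.6f}\n"
        f"yllcorner {raster.origin[1]:.6f}\n"
        f"cellsize {raster.cell_size:.6f}\n"
        f"NODATA_value {raster.nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # ASCII grids store the top (northern) row first
        np.savetxt(fh, out[::-1], fmt="%.10g")


def read_ascii_grid(path: str | Path, crs: str = "synthetic-lcc") -> GridRaster:
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    vals = np.atleast_2d(vals)[::-1].copy()
    nodata = header.get("nodata_value", -9999.0)
    vals[vals == nodata] = np.nan
    return GridRaster(
        vals,
        origin=(header["xllcorner"], header["yllcorner"]),
        cell_size=header["cellsize"],
        crs=crs,
        nodata=nodata,
    )
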