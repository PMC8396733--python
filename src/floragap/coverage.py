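"""Survey coverage in environmental space via kernel density estimation.

Sampling is adequately distributed along a climate gradient when the density
of sampling effort over that gradient resembles the density of the landscape
itself.  Both densities are estimated with a Gaussian-kernel KDE — a sum of
kernels centred at the data, normalised so the estimate is a proper PDF —
and compared with the overlap coefficient, the shared probability mass
``integral of min(f_landscape, f_effort)`` (1 = identical shapes, 0 =
disjoint).  The Kolmogorov–Smirnov distance between the two estimated CDFs
is reported alongside.

Landscape densities use one climate value per grid cell of a unit; effort
densities use the climate value at each record's cell, so cells enter
weighted by visitation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

from .bioregions import BioregionMap
from .grid import GridRaster

GRID_POINTS = 512
GRID_PAD_BANDWIDTHS = 3.0


class DegenerateInputError(ValueError):
    """KDE input has fewer than two values or zero spread."""


def bandwidth(values: np.ndarray, rule: str = "silverman") -> float:
    """Normal-reference bandwidths for a 1-D Gaussian KDE.

    silverman: 0.9 * min(sd, IQR/1.34) * n^(-1/5)  (robust to heavy tails)
    scott:     1.06 * sd * n^(-1/5)
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    sd = values.std(ddof=1)
    if rule == "silverman":
        iqr = np.subtract(*np.percentile(values, [75, 25]))
        spread = min(sd, iqr / 1.34) if iqr > 0 else sd
        return 0.9 * spread * n ** (-0.2)
    if rule == "scott":
        return 1.06 * sd * n ** (-0.2)
    raise ValueError("bandwidth rule must be 'silverman' or 'scott'")


@dataclass
class KdeCurve:
    """A Gaussian-KDE density over one climate variable on a fixed grid."""

    variable: str
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n_input: int
    values: np.ndarray = field(repr=False, default=None)

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Exact re-evaluation of the estimate at arbitrary points."""
        x = np.asarray(x, dtype=float)
        out = np.empty(x.size)
        step = max(1, 10_000_000 // max(self.values.size, 1))
        for i in range(0, x.size, step):
            blk = x[i : i + step]
            out[i : i + step] = norm.pdf(
                (blk[:, None] - self.values[None, :]) / self.bandwidth
            ).sum(axis=1) / (self.n_input * self.bandwidth)
        return out

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({self.variable: self.grid, "density": self.density})


def kde(values, variable: str = "value", bandwidth_rule: str = "silverman") -> KdeCurve:
    """Gaussian-kernel density estimate on a 512-point grid.

    The grid spans [min - 3h, max + 3h], which captures all but ~1e-3 of the
    kernel mass, so the trapezoidal integral of the curve is 1 to within 1e-3.
    Fewer than two finite values, or zero spread, is a degenerate input.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise DegenerateInputError("KDE needs at least 2 finite values")
    if values.max() == values.min():
        raise DegenerateInputError("KDE input has zero spread")
    h = bandwidth(values, bandwidth_rule)
    grid = np.linspace(
        values.min() - GRID_PAD_BANDWIDTHS * h,
        values.max() + GRID_PAD_BANDWIDTHS * h,
        GRID_POINTS,
    )
    curve = KdeCurve(
        variable=variable, grid=grid, density=None, bandwidth=h,
        n_input=values.size, values=values,
    )
    curve.density = curve.evaluate(grid)
    return curve


def _unit_cell_mask(bmap: BioregionMap | None, unit) -> np.ndarray | None:
    if bmap is None or unit is None or unit == "all":
        return None
    return bmap.units.flat() == unit


def landscape_density(
    climate: GridRaster,
    bmap: BioregionMap | None = None,
    unit="all",
    variable: str = "climate",
    bandwidth_rule: str = "silverman",
) -> KdeCurve:
    """KDE of the climate values of every cell of a unit (or the whole landscape)."""
    vals = climate.flat()
    mask = _unit_cell_mask(bmap, unit)
    if mask is not None:
        vals = vals[mask]
    if vals[np.isfinite(vals)].size < 2:
        raise DegenerateInputError(f"unit {unit!r} has fewer than 2 cells with climate values")
    return kde(vals, variable=variable, bandwidth_rule=bandwidth_rule)


def effort_density(
    records: pd.DataFrame,
    climate: GridRaster,
    unit="all",
    variable: str = "climate",
    bandwidth_rule: str = "silverman",
) -> KdeCurve:
    """KDE of the climate value at each record's cell.

    ``records`` must carry ``cell`` (flat index) and ``unit``; records with a
    sentinel cell are skipped.  Each record contributes one kernel, so cells
    are weighted by how often they were visited.
    """
    recs = records[records["cell"] >= 0]
    if unit not in (None, "all"):
        recs = recs[recs["unit"] == unit]
    if len(recs) < 2:
        raise DegenerateInputError(f"fewer than 2 records in scope for unit {unit!r}")
    vals = climate.flat()[recs["cell"].to_numpy()]
    return kde(vals, variable=variable, bandwidth_rule=bandwidth_rule)


@dataclass
class CoverageResult:
    """Shared-density-mass comparison between landscape and effort curves."""

    unit: object
    variable: str
    overlap: float
    ks_distance: float
    n_records: int
    n_cells: int


def coverage_overlap(
    landscape: KdeCurve, effort: KdeCurve, unit="all"
) -> CoverageResult:
    """Overlap coefficient (and KS distance) between two KDE curves.

    Both curves are re-evaluated exactly on the union of their grids; overlap
    is the trapezoidal integral of the pointwise minimum.  Disjoint
    evaluation ranges yield overlap 0 with a warning.
    """
    if landscape.variable != effort.variable:
        raise ValueError(
            f"curves are for different variables: {landscape.variable!r} vs {effort.variable!r}"
        )
    lo = max(landscape.grid.min(), effort.grid.min())
    hi = min(landscape.grid.max(), effort.grid.max())
    if lo >= hi:
        warnings.warn("KDE evaluation ranges are disjoint; overlap is 0", stacklevel=2)
        return CoverageResult(unit, landscape.variable, 0.0, 1.0,
                              effort.n_input, landscape.n_input)
    grid = np.union1d(landscape.grid, effort.grid)
    f1 = landscape.evaluate(grid)
    f2 = effort.evaluate(grid)
    # renormalise on the union grid so the coefficient compares shapes only
    # (the finite evaluation window truncates ~1e-4 of kernel mass)
    f1 = f1 / np.trapezoid(f1, grid)
    f2 = f2 / np.trapezoid(f2, grid)
    overlap = float(np.trapezoid(np.minimum(f1, f2), grid))
    c1 = _cdf(f1, grid)
    c2 = _cdf(f2, grid)
    ks = float(np.max(np.abs(c1 - c2)))
    return CoverageResult(
        unit=unit, variable=landscape.variable,
        overlap=min(overlap, 1.0), ks_distance=ks,
        n_records=effort.n_input, n_cells=landscape.n_input,
    )


def _cdf(density: np.ndarray, grid: np.ndarray) -> np.ndarray:
    steps = np.diff(grid)
    inc = 0.5 * (density[1:] + density[:-1]) * steps
    c = np.concatenate([[0.0], np.cumsum(inc)])
    return c / c[-1] if c[-1] > 0 else c


def coverage_table(
    records: pd.DataFrame,
    anmt: GridRaster,
    anp: GridRaster,
    bmap: BioregionMap,
    units=None,
    min_records: int = 10,
    bandwidth_rule: str = "silverman",
) -> pd.DataFrame:
    """Overlap statistics for both climate variables, landscape-wide and per unit.

    Units with fewer than ``min_records`` in-scope records, or fewer than two
    cells, are skipped (too little data for a meaningful density).
    """
    units = list(units) if units is not None else ["all"] + bmap.unit_ids
    rows = []
    for unit in units:
        for var, clim in (("ANMT", anmt), ("ANP", anp)):
            try:
                land = landscape_density(clim, bmap, unit, variable=var,
                                         bandwidth_rule=bandwidth_rule)
                sub = records if unit == "all" else records[records["unit"] == unit]
                if (sub["cell"] >= 0).sum() < min_records:
                    continue
                eff = effort_density(sub, clim, unit="all", variable=var,
                                     bandwidth_rule=bandwidth_rule)
            except DegenerateInputError:
                continue
            res = coverage_overlap(land, eff, unit=unit)
            rows.append(
                {"unit": unit, "variable": var, "overlap": res.overlap,
                 "ks_distance": res.ks_distance, "n_records": res.n_records,
                 "n_cells": res.n_cells}
            )
    return pd.DataFrame(rows)
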