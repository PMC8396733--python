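"""Analysis-unit (bioregion) map construction and point-to-unit assignment.

A bioregion is the intersection of a biome class with a geographic region
(e.g. "Andean moist forest").  The map is built by overlaying a biome raster
with a region raster through a user-supplied definition table, then
overriding human-transformed cells with a single reserved unit id, which is
treated as a bioregion in its own right in all downstream tallies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import OUTSIDE, GridRaster, require_same_grid

logger = logging.getLogger(__name__)

#: Sentinel unit id for cells/points with no bioregion.
MISSING_UNIT = -1

#: Default reserved id for the merged transformed-areas unit.
TRANSFORMED_ID = 14


@dataclass
class BioregionMap:
    """Unit-id raster plus its label table.

    ``units.values`` is an integer raster; :data:`MISSING_UNIT` marks cells
    whose (biome, region) combination was absent from the definition table.
    """

    units: GridRaster
    labels: dict[int, str] = field(default_factory=dict)
    transformed_id: int = TRANSFORMED_ID

    def __post_init__(self) -> None:
        present = set(np.unique(self.units.values)) - {MISSING_UNIT}
        unlabeled = present - set(self.labels)
        if unlabeled:
            raise ValueError(f"unit id(s) without a label: {sorted(unlabeled)}")

    @property
    def unit_ids(self) -> list[int]:
        return sorted(self.labels)

    def cells_per_unit(self) -> pd.Series:
        """Number of grid cells per unit id (all labelled units, zeros included)."""
        flat = self.units.flat()
        counts = pd.Series(flat[flat != MISSING_UNIT]).value_counts()
        return counts.reindex(self.unit_ids, fill_value=0).astype(int)


def overlay_biome_region(
    biome: GridRaster,
    region: GridRaster,
    definition_table: pd.DataFrame,
    transformed_id: int = TRANSFORMED_ID,
) -> BioregionMap:
    """Combine biome and region rasters into analysis units via a lookup table.

    ``definition_table`` has columns (biome_id, region_id, unit_id, unit_name)
    and may map several combinations to one unit.  Combinations present in
    the data but absent from the table become :data:`MISSING_UNIT`; their
    count is logged.
    """
    require_same_grid(biome, region)
    required = {"biome_id", "region_id", "unit_id", "unit_name"}
    if not required.issubset(definition_table.columns):
        raise ValueError(f"definition table needs columns {sorted(required)}")

    lut = {
        (int(r.biome_id), int(r.region_id)): int(r.unit_id)
        for r in definition_table.itertuples()
    }
    b = biome.values.astype(int).reshape(-1)
    g = region.values.astype(int).reshape(-1)
    units = np.array([lut.get((bi, gi), MISSING_UNIT) for bi, gi in zip(b, g)])
    n_missing = int((units == MISSING_UNIT).sum())
    if n_missing:
        logger.info("overlay: %d cell(s) with undefined (biome, region) combination", n_missing)

    labels = {
        int(r.unit_id): str(r.unit_name) for r in definition_table.itertuples()
    }
    unit_raster = GridRaster(
        units.reshape(biome.values.shape),
        origin=biome.origin,
        cell_size=biome.cell_size,
        crs=biome.crs,
    )
    labels.setdefault(transformed_id, "Transformed areas")
    return BioregionMap(unit_raster, labels=labels, transformed_id=transformed_id)


def apply_transformed_mask(bmap: BioregionMap, mask: GridRaster) -> BioregionMap:
    """Override masked cells with the reserved transformed-areas unit id.

    Idempotent; cells outside the mask are untouched.
    """
    require_same_grid(bmap.units, mask)
    vals = bmap.units.values.copy()
    vals[mask.values.astype(bool)] = bmap.transformed_id
    labels = dict(bmap.labels)
    labels.setdefault(bmap.transformed_id, "Transformed areas")
    new_units = GridRaster(
        vals, origin=bmap.units.origin, cell_size=bmap.units.cell_size, crs=bmap.units.crs
    )
    return BioregionMap(new_units, labels=labels, transformed_id=bmap.transformed_id)


def assign_bioregion(cell_indices: np.ndarray, bmap: BioregionMap) -> np.ndarray:
    """Unit id per point from its flat cell index; sentinel in, sentinel out."""
    cell_indices = np.asarray(cell_indices)
    flat = bmap.units.flat()
    out = np.full(cell_indices.shape, MISSING_UNIT, dtype=int)
    valid = cell_indices != OUTSIDE
    out[valid] = flat[cell_indices[valid]]
    return out
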