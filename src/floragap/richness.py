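"""Per-cell tallies, mean species richness by survey subset, and survey completeness.

Sampling effort is measured as the number of unique observations per grid
cell.  A cell is *surveyed* when it holds at least one record and
*well-surveyed* at threshold T when it holds at least T records (the low /
moderate / high thresholds are 10 / 25 / 50, with 25 the headline
definition).  Mean species richness (the species/cells ratio) is reported
over three extents: all cells of a unit (empty cells count as zero),
surveyed cells only, and well-surveyed cells only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bioregions import MISSING_UNIT, BioregionMap

DEFAULT_THRESHOLDS = (10, 25, 50)
WELL_SURVEYED_DEFAULT = 25


def summarize_cells(records: pd.DataFrame) -> pd.DataFrame:
    """Per-occupied-cell tallies of records and distinct species.

    ``records`` must carry ``cell`` (flat cell index), ``unit`` (bioregion
    id), ``accepted_name`` and, if use information is attached,
    ``is_useful``.  Returns one row per occupied cell with columns
    cell, unit, n_records, n_species, n_useful_records, n_useful_species.
    Records outside the grid (sentinel cell) are excluded.
    """
    required = {"cell", "unit", "accepted_name"}
    if not required.issubset(records.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    recs = records[records["cell"] >= 0]
    grouped = recs.groupby("cell", sort=True)
    out = grouped.agg(
        unit=("unit", "first"),
        n_records=("accepted_name", "size"),
        n_species=("accepted_name", "nunique"),
    ).reset_index()
    if "is_useful" in recs.columns:
        useful = recs[recs["is_useful"]]
        ug = useful.groupby("cell").agg(
            n_useful_records=("accepted_name", "size"),
            n_useful_species=("accepted_name", "nunique"),
        )
        out = out.merge(ug, on="cell", how="left")
        out[["n_useful_records", "n_useful_species"]] = (
            out[["n_useful_records", "n_useful_species"]].fillna(0).astype(int)
        )
    else:
        out["n_useful_records"] = 0
        out["n_useful_species"] = 0
    return out


def _subset_cells(
    cells: pd.DataFrame, subset: str, which: str, threshold: int
) -> pd.DataFrame:
    rec_col = "n_records" if which == "all_plants" else "n_useful_records"
    if subset == "all":
        return cells
    if subset == "surveyed":
        return cells[cells[rec_col] >= 1]
    if subset == "well_surveyed":
        return cells[cells[rec_col] >= threshold]
    raise ValueError("subset must be 'all', 'surveyed' or 'well_surveyed'")


def mean_richness(
    cells: pd.DataFrame,
    bmap: BioregionMap,
    unit: int,
    subset: str = "all",
    which: str = "all_plants",
    threshold: int = WELL_SURVEYED_DEFAULT,
) -> float:
    """Mean species per cell in one unit over the chosen cell subset.

    ``subset='all'`` divides summed richness by *all* cells of the unit in
    the bioregion map (unoccupied cells contribute zero species);
    ``'surveyed'`` / ``'well_surveyed'`` average only over qualifying cells.
    Returns NaN when the qualifying set is empty.
    """
    if which not in ("all_plants", "useful"):
        raise ValueError("which must be 'all_plants' or 'useful'")
    if unit not in bmap.labels:
        raise KeyError(f"unknown unit id {unit}")
    sp_col = "n_species" if which == "all_plants" else "n_useful_species"
    unit_cells = cells[cells["unit"] == unit]
    if subset == "all":
        total_cells = int(bmap.cells_per_unit().get(unit, 0))
        if total_cells == 0:
            return float("nan")
        return float(unit_cells[sp_col].sum() / total_cells)
    sub = _subset_cells(unit_cells, subset, which, threshold)
    if len(sub) == 0:
        return float("nan")
    return float(sub[sp_col].mean())


def richness_table(
    cells: pd.DataFrame,
    bmap: BioregionMap,
    threshold: int = WELL_SURVEYED_DEFAULT,
) -> pd.DataFrame:
    """Mean richness per unit for every (subset, dataset) combination."""
    rows = []
    for unit in bmap.unit_ids:
        row = {"unit": unit, "unit_name": bmap.labels[unit]}
        for which in ("all_plants", "useful"):
            for subset in ("all", "surveyed", "well_surveyed"):
                row[f"mean_richness_{which}_{subset}"] = mean_richness(
                    cells, bmap, unit, subset=subset, which=which, threshold=threshold
                )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CompletenessReport:
    """Per-unit surveyed / well-surveyed cell counts and percentages."""

    table: pd.DataFrame
    thresholds: tuple[int, ...]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def completeness(
    cells: pd.DataFrame,
    bmap: BioregionMap,
    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS,
) -> CompletenessReport:
    """Survey completeness per unit, for all plants and the useful subset.

    For each unit and dataset: total cells (of the unit in the map), surveyed
    cells, well-surveyed cells at each threshold, ``pct_surveyed`` =
    surveyed/total x 100 and, at each threshold, the share of well-surveyed
    cells among *surveyed* cells (``pct_well_T_of_surveyed``) plus the share
    among all cells (``pct_well_T_of_total``) since reporting conventions for
    the denominator differ.  Units with no surveyed cells report 0 with the
    ``no_surveyed_cells`` flag set.
    """
    thresholds = tuple(thresholds)
    if any(t <= 0 for t in thresholds) or list(thresholds) != sorted(set(thresholds)):
        raise ValueError("thresholds must be strictly increasing positive integers")
    totals = bmap.cells_per_unit()
    rows = []
    for unit in bmap.unit_ids:
        unit_cells = cells[cells["unit"] == unit]
        total = int(totals.get(unit, 0))
        for which, rec_col in (("all_plants", "n_records"), ("useful", "n_useful_records")):
            surveyed = int((unit_cells[rec_col] >= 1).sum())
            row = {
                "unit": unit,
                "unit_name": bmap.labels[unit],
                "dataset": which,
                "total_cells": total,
                "surveyed_cells": surveyed,
                "pct_surveyed": 100.0 * surveyed / total if total else 0.0,
                "no_surveyed_cells": surveyed == 0,
            }
            for t in thresholds:
                well = int((unit_cells[rec_col] >= t).sum())
                row[f"well_surveyed_{t}"] = well
                row[f"pct_well_{t}_of_surveyed"] = (
                    100.0 * well / surveyed if surveyed else 0.0
                )
                row[f"pct_well_{t}_of_total"] = 100.0 * well / total if total else 0.0
            rows.append(row)
    return CompletenessReport(pd.DataFrame(rows), thresholds)


def per_species_statistics(records: pd.DataFrame) -> dict:
    """Record-count statistics over deduplicated records.

    Returns mean records per species, the number and percentage of
    single-locality species (point endemics: exactly one unique coordinate),
    and the species/record totals.  NaNs are reported when there are no
    species.
    """
    n_records = int(len(records))
    species = records.groupby("accepted_name")
    n_species = int(species.ngroups)
    if n_species == 0:
        return {
            "n_records": 0, "n_species": 0,
            "mean_records_per_species": float("nan"),
            "single_locality_species": 0,
            "pct_single_locality": float("nan"),
        }
    localities = records.drop_duplicates(subset=["accepted_name", "lat", "lon"])
    loc_counts = localities.groupby("accepted_name").size()
    single = int((loc_counts == 1).sum())
    return {
        "n_records": n_records,
        "n_species": n_species,
        "mean_records_per_species": n_records / n_species,
        "single_locality_species": single,
        "pct_single_locality": 100.0 * single / n_species,
    }
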