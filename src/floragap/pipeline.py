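"""End-to-end pipeline: simulate -> clean -> gridify -> richness -> usage -> coverage -> report.

Each stage reads only the artifacts of earlier stages from the output
directory, writes its own tables plus a JSON manifest (config hash, seed,
row counts), and is deterministic given the config, so re-running a stage
with the same config reproduces its outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bioregions, coverage, occurrences, richness, synthetic, usage
from .grid import assign_cells, read_ascii_grid, write_ascii_grid
from .projection import get_projection

logger = logging.getLogger(__name__)

STAGES = ("simulate", "clean", "gridify", "richness", "usage", "coverage", "report")


class DependencyError(RuntimeError):
    """An upstream artifact is missing; the message names the stage to run first."""


@dataclass
class PipelineConfig:
    """Flat configuration for the whole pipeline (YAML-loadable, CLI-overridable)."""

    outdir: str = "floragap_out"
    seed: int = 0

    # landscape / simulation
    width_cells: int = 50
    height_cells: int = 50
    cell_size_km: float = 10.0
    n_biomes: int = 5
    n_regions: int = 3
    transformed_fraction: float = 0.15
    n_species: int = 2000
    n_records: int = 50_000
    effort: str = "biased"          # "uniform" | "biased"

    # cleaning
    dedup_precision: int = 4
    unmatched_policy: str = "discard"
    cleaning_rules: list[str] = field(
        default_factory=lambda: ["coord_missing", "coord_out_of_range",
                                 "zero_zero", "equal_lat_lon"]
    )

    # gridding
    crs: str = "south-america-lcc"

    # richness / completeness
    thresholds: list[int] = field(default_factory=lambda: [10, 25, 50])
    well_surveyed_threshold: int = 25

    # usage clustering
    cluster_method: str = "average"
    cluster_metric: str = "euclidean"
    cluster_log: bool = True

    # coverage
    kde_bandwidth_rule: str = "silverman"
    coverage_min_records: int = 10

    def __post_init__(self) -> None:
        t = list(self.thresholds)
        if t != sorted(set(t)) or any(x <= 0 for x in t):
            raise ValueError("thresholds must be strictly increasing positive integers")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def landscape(self) -> synthetic.LandscapeConfig:
        return synthetic.LandscapeConfig(
            width_cells=self.width_cells,
            height_cells=self.height_cells,
            cell_size_km=self.cell_size_km,
            n_biomes=self.n_biomes,
            n_regions=self.n_regions,
            transformed_fraction=self.transformed_fraction,
            seed=self.seed,
        )

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class Pipeline:
    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        for sub in ("data", "tables", "rasters", "manifests"):
            (self.outdir / sub).mkdir(parents=True, exist_ok=True)

    # -- helpers -------------------------------------------------------------

    def _need(self, path: Path, produced_by: str) -> Path:
        if not path.exists():
            raise DependencyError(
                f"missing artifact {path}; run the '{produced_by}' stage first"
            )
        return path

    def _manifest(self, stage: str, extra: dict) -> None:
        payload = {
            "stage": stage,
            "seed": self.config.seed,
            "config_digest": self.config.digest(),
            **extra,
        }
        path = self.outdir / "manifests" / f"{stage}.json"
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        logger.info("stage %s done: %s", stage, extra)

    # -- stages --------------------------------------------------------------

    def simulate(self) -> None:
        ds = synthetic.simulate_dataset(
            self.config.landscape(),
            n_species=self.config.n_species,
            n_records=self.config.n_records,
            effort=self.config.effort,
        )
        ds.write(self.outdir / "data")
        synthetic.default_definition_table(self.config.landscape()).to_csv(
            self.outdir / "data" / "definition_table.csv", index=False
        )
        self._manifest("simulate", {
            "n_species": len(ds.pool),
            "n_records": int(len(ds.records)),
            "corruption_counts": ds.truth["corruption_counts"],
        })

    def clean(self) -> None:
        data = self.outdir / "data"
        occ_path = self._need(data / "occurrences.csv", "simulate")
        records = occurrences.read_occurrences(occ_path)
        table = occurrences.NameResolutionTable.from_csv(
            self._need(data / "name_table.csv", "simulate")
        )
        resolved = occurrences.resolve_names(records, table, self.config.unmatched_policy)
        res_report = resolved.attrs.get("resolution_report", {})
        kept, clean_report = occurrences.clean_coordinates(
            resolved, rules=list(self.config.cleaning_rules)
        )
        deduped = occurrences.deduplicate(kept, self.config.dedup_precision)
        use_table = occurrences.UseTable.from_csv(
            self._need(data / "use_table.csv", "simulate")
        )
        final = occurrences.attach_uses(deduped, use_table)
        out = final.copy()
        out["uses"] = out["uses"].map(lambda s: "|".join(sorted(s)))
        out.to_csv(self.outdir / "tables" / "cleaned_records.csv", index=False)
        self._manifest("clean", {
            "resolution": res_report,
            "cleaning": clean_report.to_dict(),
            "deduplicated": int(len(deduped)),
            "useful_records": int(final["is_useful"].sum()),
        })

    def _read_cleaned(self) -> pd.DataFrame:
        path = self._need(self.outdir / "tables" / "cleaned_records.csv", "clean")
        df = pd.read_csv(path, keep_default_na=False, dtype={"flags": str, "uses": str})
        df["lat"] = pd.to_numeric(df["lat"])
        df["lon"] = pd.to_numeric(df["lon"])
        df["uses"] = df["uses"].map(
            lambda s: frozenset(s.split("|")) if s else frozenset()
        )
        df["is_useful"] = df["is_useful"].astype(str).str.lower() == "true"
        return df

    def _build_bioregion_map(self) -> bioregions.BioregionMap:
        data = self.outdir / "data"
        biome = read_ascii_grid(self._need(data / "biome.asc", "simulate"), crs=self.config.crs)
        region = read_ascii_grid(data / "region.asc", crs=self.config.crs)
        transformed = read_ascii_grid(data / "transformed.asc", crs=self.config.crs)
        deftab = pd.read_csv(data / "definition_table.csv")
        bmap = bioregions.overlay_biome_region(biome, region, deftab)
        return bioregions.apply_transformed_mask(bmap, transformed)

    def gridify(self) -> None:
        records = self._read_cleaned()
        bmap = self._build_bioregion_map()
        proj = get_projection(self.config.crs)
        x, y = proj.forward(records["lon"].to_numpy(), records["lat"].to_numpy())
        cells = assign_cells(x, y, bmap.units)
        units = bioregions.assign_bioregion(cells, bmap)
        out = records.copy()
        out["cell"] = cells
        out["unit"] = units
        out["uses"] = out["uses"].map(lambda s: "|".join(sorted(s)))
        out.to_csv(self.outdir / "tables" / "assigned_records.csv", index=False)
        write_ascii_grid(bmap.units, self.outdir / "rasters" / "bioregions.asc")
        pd.DataFrame(
            sorted(bmap.labels.items()), columns=["unit_id", "unit_name"]
        ).to_csv(self.outdir / "tables" / "unit_labels.csv", index=False)
        self._manifest("gridify", {
            "n_records": int(len(out)),
            "outside_grid": int((cells < 0).sum()),
            "no_unit": int((units < 0).sum()) - int((cells < 0).sum()),
        })

    def _read_assigned(self) -> pd.DataFrame:
        path = self._need(self.outdir / "tables" / "assigned_records.csv", "gridify")
        df = pd.read_csv(path, keep_default_na=False, dtype={"flags": str, "uses": str})
        for col in ("lat", "lon"):
            df[col] = pd.to_numeric(df[col])
        for col in ("cell", "unit"):
            df[col] = pd.to_numeric(df[col]).astype(int)
        df["uses"] = df["uses"].map(lambda s: frozenset(s.split("|")) if s else frozenset())
        df["is_useful"] = df["is_useful"].astype(str).str.lower() == "true"
        return df

    def richness(self) -> None:
        records = self._read_assigned()
        bmap = self._build_bioregion_map()
        cells = richness.summarize_cells(records)
        cells.to_csv(self.outdir / "tables" / "cell_summaries.csv", index=False)
        rich = richness.richness_table(
            cells, bmap, threshold=self.config.well_surveyed_threshold
        )
        rich.to_csv(self.outdir / "tables" / "bioregion_summaries.csv", index=False)
        comp = richness.completeness(cells, bmap, tuple(self.config.thresholds))
        comp.to_csv(self.outdir / "tables" / "completeness.csv")
        stats_all = richness.per_species_statistics(records)
        stats_useful = richness.per_species_statistics(records[records["is_useful"]])
        (self.outdir / "tables" / "per_species_statistics.json").write_text(
            json.dumps({"all_plants": stats_all, "useful": stats_useful},
                       indent=2, sort_keys=True)
        )
        self._manifest("richness", {
            "occupied_cells": int(len(cells)),
            "units": int(cells["unit"].nunique()),
        })

    def usage(self) -> None:
        records = self._read_assigned()
        stats = usage.category_totals(records)
        stats.to_csv(self.outdir / "tables" / "category_stats.csv",
                     index_label="category")
        mat = usage.bioregion_use_matrix(records)
        mat.to_csv(self.outdir / "tables" / "use_matrix.csv", index_label="unit")
        if mat.shape[0] >= 2 and mat.shape[1] >= 2:
            clust = usage.cluster_matrix(
                mat, method=self.config.cluster_method,
                metric=self.config.cluster_metric,
                log_transform=self.config.cluster_log,
            )
            (self.outdir / "tables" / "use_matrix_rows.nwk").write_text(
                usage.linkage_to_newick(clust.row_linkage, [str(i) for i in mat.index])
            )
            (self.outdir / "tables" / "use_matrix_cols.nwk").write_text(
                usage.linkage_to_newick(clust.col_linkage, list(mat.columns))
            )
        fam = usage.top_families(records[["accepted_name", "family", "is_useful"]])
        fam.to_csv(self.outdir / "tables" / "family_counts.csv", index=False)
        self._manifest("usage", {
            "categories": int(len(stats)),
            "matrix_shape": list(mat.shape),
        })

    def coverage(self) -> None:
        records = self._read_assigned()
        bmap = self._build_bioregion_map()
        data = self.outdir / "data"
        anmt = read_ascii_grid(self._need(data / "anmt.asc", "simulate"), crs=self.config.crs)
        anp = read_ascii_grid(data / "anp.asc", crs=self.config.crs)
        tab = coverage.coverage_table(
            records, anmt, anp, bmap,
            min_records=self.config.coverage_min_records,
            bandwidth_rule=self.config.kde_bandwidth_rule,
        )
        tab.to_csv(self.outdir / "tables" / "coverage.csv", index=False)
        useful = records[records["is_useful"]]
        if len(useful) >= self.config.coverage_min_records:
            tab_u = coverage.coverage_table(
                useful, anmt, anp, bmap,
                min_records=self.config.coverage_min_records,
                bandwidth_rule=self.config.kde_bandwidth_rule,
            )
            tab_u.to_csv(self.outdir / "tables" / "coverage_useful.csv", index=False)
        self._manifest("coverage", {"rows": int(len(tab))})

    def report(self) -> None:
        tables = self.outdir / "tables"
        self._need(tables / "completeness.csv", "richness")
        self._need(tables / "category_stats.csv", "usage")
        self._need(tables / "coverage.csv", "coverage")
        comp = pd.read_csv(tables / "completeness.csv")
        stats = json.loads((tables / "per_species_statistics.json").read_text())
        cov = pd.read_csv(tables / "coverage.csv")
        t = self.config.well_surveyed_threshold
        summary = {
            "per_species": stats,
            "median_pct_well_surveyed_of_surveyed": float(
                comp.loc[comp["dataset"] == "useful", f"pct_well_{t}_of_surveyed"].median()
            ),
            "landscape_overlap": {
                row["variable"]: row["overlap"]
                for _, row in cov[cov["unit"] == "all"].iterrows()
            },
        }
        (self.outdir / "report.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True)
        )
        self._manifest("report", {"written": "report.json"})

    # -- driver --------------------------------------------------------------

    def run(self, stage: str = "all") -> None:
        if stage == "all":
            for s in STAGES:
                getattr(self, s)()
        elif stage in STAGES:
            getattr(self, stage)()
        else:
            raise ValueError(f"unknown stage {stage!r}; choose from {STAGES + ('all',)}")
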