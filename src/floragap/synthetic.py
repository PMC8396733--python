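"""Synthetic study system: climate, biome/region layers, species pool, biased sampling.

The generator emulates the statistical structure a national useful-plant gap
analysis assumes, on a rectangular landscape instead of real geography:

* two smooth climate surfaces — annual mean temperature (ANMT, deg C) and total
  annual precipitation (ANP, mm/yr) — as orthogonal monotone gradients plus
  seeded noise;
* a biome layer (quantile bins of a joint climate index), a region layer
  (contiguous bands) and a clustered human-transformed mask covering a target
  fraction of each region;
* a species pool with Gaussian climatic niches, circular geographic ranges,
  a configurable fraction of useful species with multi-category use sets
  drawn from per-category marginal probabilities, and a configurable fraction
  of point endemics known from a single locality;
* occurrence records drawn cell-by-cell from a sampling-effort surface, with
  species chosen proportionally to niche suitability, plus seeded verbatim-
  name corruption (synonyms, misspellings, unresolvable names) and sparse
  coordinate corruption for the cleaning stage to catch.

The landscape is anchored in real coordinates: planar cell positions are
mapped to WGS84 lon/lat through the continental Lambert conformal conic, so
the downstream projection and gridding stages run exactly as they would on
real data.  All randomness flows from one integer seed through named
sub-streams, so equal seeds give bit-identical datasets.

Default conditions mirror the shape of a national vascular-plant snapshot at
reduced scale: 2,000 species of which ~16% are useful, use-category marginals
matching the national useful-plant tabulation (Medicines 0.763, Materials
0.381, ...), ~19.7% point endemics, and 50,000 records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import GridRaster, write_ascii_grid
from .occurrences import USE_CATEGORIES, NameResolutionTable, UseTable
from .projection import SOUTH_AMERICA_LCC, get_projection

#: Per-category probability that a useful species carries the category,
#: matching the national tabulation of useful-plant species shares.
DEFAULT_USE_MARGINALS = {
    "MEDICINES": 0.763,
    "MATERIALS": 0.381,
    "ENVIRONMENTAL USES": 0.319,
    "HUMAN FOOD": 0.259,
    "ANIMAL FOOD": 0.157,
    "GENE SOURCES": 0.140,
    "POISONS": 0.121,
    "SOCIAL USES": 0.088,
    "FUELS": 0.061,
    "INVERTEBRATE FOOD": 0.037,
}

#: Useful species as a share of the whole flora (~3,870 of 23,961).
DEFAULT_USEFUL_FRACTION = 0.16
#: Share of species known from a single locality (~4,721 of 23,961).
DEFAULT_ENDEMIC_FRACTION = 0.197

_STREAMS = {
    "climate": 0,
    "layers": 1,
    "pool": 2,
    "names": 3,
    "occurrences": 4,
    "effort": 5,
}


class ConfigurationError(ValueError):
    pass


class SamplingError(RuntimeError):
    """Raised when no (cell, species) pair has positive sampling probability."""


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child generator of the master seed; streams are independent."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[name],)))


@dataclass(frozen=True)
class LandscapeConfig:
    """Dimensions, climate ranges and layer structure of the synthetic landscape."""

    width_cells: int = 50
    height_cells: int = 50
    cell_size_km: float = 10.0
    temp_range: tuple[float, float] = (5.0, 28.0)
    precip_range: tuple[float, float] = (500.0, 8000.0)
    temp_noise_sd: float = 1.0
    precip_noise_sd: float = 250.0
    n_biomes: int = 5
    n_regions: int = 3
    transformed_fraction: float = 0.15
    anchor_lon: float = -73.0
    anchor_lat: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_cells < 2 or self.height_cells < 2:
            raise ConfigurationError("landscape needs at least 2x2 cells")
        if not (0 <= self.transformed_fraction < 1):
            raise ConfigurationError("transformed_fraction must be in [0, 1)")
        if self.temp_range[0] > self.temp_range[1]:
            raise ConfigurationError("temp_range min must not exceed max")
        if self.precip_range[0] > self.precip_range[1]:
            raise ConfigurationError("precip_range min must not exceed max")
        if self.cell_size_km <= 0:
            raise ConfigurationError("cell_size_km must be positive")

    @property
    def n_cells(self) -> int:
        return self.width_cells * self.height_cells

    @property
    def cell_size_m(self) -> float:
        return self.cell_size_km * 1000.0

    def grid_origin_m(self, projection=SOUTH_AMERICA_LCC) -> tuple[float, float]:
        """Projected lower-left corner: the landscape is anchored at (anchor_lon, anchor_lat)."""
        x, y = get_projection(projection).forward(self.anchor_lon, self.anchor_lat)
        return float(x), float(y)


@dataclass
class SyntheticSpecies:
    accepted_name: str
    family: str
    niche_center: tuple[float, float]        # (ANMT deg C, ANP mm)
    niche_breadth: tuple[float, float]       # Gaussian SDs, same units
    range_center: tuple[float, float]        # projected metres
    range_radius_m: float
    is_useful: bool
    uses: frozenset
    is_point_endemic: bool

    def __post_init__(self) -> None:
        if self.is_useful != bool(self.uses):
            raise ValueError("uses must be non-empty iff is_useful")
        if min(self.niche_breadth) <= 0:
            raise ValueError("niche_breadth must be strictly positive")


@dataclass
class EffortSurface:
    """Per-cell sampling-effort weights on the landscape grid, summing to 1."""

    weights: np.ndarray  # flat, length n_cells, row 0 (south) first

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
        if (self.weights < 0).any():
            raise ValueError("effort weights must be non-negative")
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("effort weights must have positive total")
        if abs(total - 1.0) > 1e-9:
            self.weights = self.weights / total

    @classmethod
    def uniform(cls, config: LandscapeConfig) -> "EffortSurface":
        return cls(np.full(config.n_cells, 1.0 / config.n_cells))

    @classmethod
    def access_biased(
        cls,
        config: LandscapeConfig,
        n_access_points: int = 5,
        decay_km: float = 50.0,
        rng: np.random.Generator | None = None,
    ) -> "EffortSurface":
        """Road-access stand-in: weights decay exponentially with distance to
        the nearest of k seeded access points."""
        rng = rng if rng is not None else substream(config.seed, "effort")
        xs = (np.arange(config.width_cells) + 0.5) * config.cell_size_km
        ys = (np.arange(config.height_cells) + 0.5) * config.cell_size_km
        gx, gy = np.meshgrid(xs, ys)
        ax = rng.uniform(0, config.width_cells * config.cell_size_km, n_access_points)
        ay = rng.uniform(0, config.height_cells * config.cell_size_km, n_access_points)
        d = np.min(
            np.sqrt((gx[..., None] - ax) ** 2 + (gy[..., None] - ay) ** 2), axis=-1
        )
        return cls(np.exp(-d / decay_km).reshape(-1))


# ---------------------------------------------------------------------------
# Climate and categorical layers


def generate_climate(
    config: LandscapeConfig, projection=SOUTH_AMERICA_LCC
) -> tuple[GridRaster, GridRaster]:
    """ANMT gradient along x, ANP gradient along y, plus seeded noise, clipped to range."""
    rng = substream(config.seed, "climate")
    nr, nc = config.height_cells, config.width_cells
    tmin, tmax = config.temp_range
    pmin, pmax = config.precip_range

    col_frac = (np.arange(nc) + 0.5) / nc
    row_frac = (np.arange(nr) + 0.5) / nr
    anmt = np.tile(tmin + (tmax - tmin) * col_frac, (nr, 1))
    anp = np.tile((pmin + (pmax - pmin) * row_frac)[:, None], (1, nc))
    anmt = anmt + rng.normal(0.0, config.temp_noise_sd, size=(nr, nc))
    anp = anp + rng.normal(0.0, config.precip_noise_sd, size=(nr, nc))
    anmt = np.clip(anmt, tmin, tmax)
    anp = np.clip(anp, pmin, pmax)

    origin = config.grid_origin_m(projection)
    crs = "south-america-lcc"
    make = lambda v: GridRaster(v, origin=origin, cell_size=config.cell_size_m, crs=crs)
    return make(anmt), make(anp)


def generate_layers(
    config: LandscapeConfig, anmt: GridRaster, anp: GridRaster
) -> tuple[GridRaster, GridRaster, GridRaster]:
    """Biome, region and transformed-mask rasters on the climate grid.

    Biomes are quantile bins (ids 1..n_biomes) of a standardized joint
    climate index, so they track the climate field like real biomes track
    energy and water.  Regions are contiguous vertical bands (ids
    1..n_regions).  The transformed mask grows seeded clustered patches until
    it covers round(transformed_fraction * cells) of each region exactly.
    """
    if config.n_biomes > config.n_cells or config.n_regions > config.n_cells:
        raise ConfigurationError("more biome/region classes than grid cells")
    if not anmt.same_grid(anp):
        raise ValueError("climate rasters must share one grid")
    rng = substream(config.seed, "layers")
    nr, nc = anmt.values.shape

    def z(v):
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    index = z(anmt.values) + z(anp.values)
    qs = np.quantile(index, np.linspace(0, 1, config.n_biomes + 1)[1:-1])
    biome = np.digitize(index, qs) + 1  # ids 1..n_biomes

    col = np.tile(np.arange(nc), (nr, 1))
    region = (col * config.n_regions) // nc + 1  # ids 1..n_regions

    mask = np.zeros((nr, nc), dtype=bool)
    for rid in range(1, config.n_regions + 1):
        cells = np.argwhere(region == rid)
        target = int(round(config.transformed_fraction * len(cells)))
        if target == 0:
            continue
        in_region = {tuple(c) for c in cells}
        chosen: set[tuple[int, int]] = set()
        frontier: list[tuple[int, int]] = []
        while len(chosen) < target:
            if not frontier:
                # start a new patch at a random untransformed cell of the region
                free = sorted(in_region - chosen)
                frontier.append(free[rng.integers(len(free))])
            i = rng.integers(len(frontier))
            r, c = frontier.pop(i)
            if (r, c) in chosen:
                continue
            chosen.add((r, c))
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                nb = (r + dr, c + dc)
                if nb in in_region and nb not in chosen:
                    frontier.append(nb)
        rows, cols_ = zip(*chosen)
        mask[list(rows), list(cols_)] = True

    make = lambda v: GridRaster(v, origin=anmt.origin, cell_size=anmt.cell_size, crs=anmt.crs)
    return make(biome), make(region), make(mask.astype(int))


# ---------------------------------------------------------------------------
# Species pool


def _family_pool(n_families: int) -> tuple[list[str], np.ndarray]:
    """Zipf-weighted family pool: family 1 is the planted most-speciose family."""
    names = [f"Familia{k:03d}" for k in range(1, n_families + 1)]
    w = 1.0 / np.arange(1, n_families + 1)
    return names, w / w.sum()


def generate_species_pool(
    config: LandscapeConfig,
    n_species: int = 2000,
    useful_fraction: float = DEFAULT_USEFUL_FRACTION,
    use_marginals: dict[str, float] | None = None,
    endemic_fraction: float = DEFAULT_ENDEMIC_FRACTION,
    n_families: int = 40,
) -> list[SyntheticSpecies]:
    """Draw the species pool.

    Each useful species draws each of the 10 categories independently with
    its marginal probability (re-drawn until non-empty), so species can hold
    several uses and category species-counts do not sum to the useful total —
    the overlap structure the category tabulation downstream must respect.
    """
    use_marginals = dict(DEFAULT_USE_MARGINALS if use_marginals is None else use_marginals)
    bad = set(use_marginals) - set(USE_CATEGORIES)
    if bad:
        raise ConfigurationError(f"unknown use categories: {sorted(bad)}")
    for k, p in use_marginals.items():
        if not (0 <= p <= 1):
            raise ConfigurationError(f"marginal for {k} outside [0, 1]")
    if not (0 <= useful_fraction <= 1) or not (0 <= endemic_fraction <= 1):
        raise ConfigurationError("fractions must lie in [0, 1]")

    rng = substream(config.seed, "pool")
    fam_names, fam_w = _family_pool(n_families)
    tmin, tmax = config.temp_range
    pmin, pmax = config.precip_range
    x0, y0 = config.grid_origin_m()
    width_m = config.width_cells * config.cell_size_m
    height_m = config.height_cells * config.cell_size_m

    cats = [c for c in USE_CATEGORIES if use_marginals.get(c, 0.0) > 0]
    probs = np.array([use_marginals[c] for c in cats])

    pool: list[SyntheticSpecies] = []
    for i in range(n_species):
        useful = bool(rng.random() < useful_fraction)
        uses: frozenset = frozenset()
        if useful:
            if len(cats) == 0:
                useful, uses = False, frozenset()
            else:
                draw = np.zeros(len(cats), dtype=bool)
                while not draw.any():
                    draw = rng.random(len(cats)) < probs
                uses = frozenset(np.array(cats)[draw])
        endemic = bool(rng.random() < endemic_fraction)
        breadth_t = max((tmax - tmin), 1e-6) * rng.uniform(0.08, 0.30)
        breadth_p = max((pmax - pmin), 1e-6) * rng.uniform(0.08, 0.30)
        pool.append(
            SyntheticSpecies(
                accepted_name=f"Planta species{i + 1:05d}",
                family=fam_names[rng.choice(len(fam_names), p=fam_w)],
                niche_center=(rng.uniform(tmin, tmax), rng.uniform(pmin, pmax)),
                niche_breadth=(breadth_t, breadth_p),
                range_center=(x0 + rng.uniform(0, width_m), y0 + rng.uniform(0, height_m)),
                range_radius_m=float(rng.uniform(0.15, 0.6) * max(width_m, height_m)),
                is_useful=useful,
                uses=uses,
                is_point_endemic=endemic,
            )
        )
    return pool


def pool_to_frame(pool: list[SyntheticSpecies]) -> pd.DataFrame:
    rows = []
    for sp in pool:
        d = asdict(sp)
        d["uses"] = "|".join(sorted(sp.uses))
        rows.append(d)
    return pd.DataFrame(rows)


def build_use_table(pool: list[SyntheticSpecies]) -> UseTable:
    rows = [
        {"accepted_name": sp.accepted_name, "category": cat}
        for sp in pool
        if sp.is_useful
        for cat in sorted(sp.uses)
    ]
    return UseTable(pd.DataFrame(rows, columns=["accepted_name", "category"]))


def _misspell(name: str, rng: np.random.Generator) -> str:
    """Drop one interior letter — a deterministic, resolvable corruption."""
    i = int(rng.integers(1, len(name) - 1))
    return name[:i] + name[i + 1 :]


def build_name_table(
    pool: list[SyntheticSpecies],
    seed: int,
    n_unresolved: int = 20,
) -> NameResolutionTable:
    """Resolution table: accepted row, one synonym and one misspelling per
    species, plus unresolvable junk names the resolver must discard."""
    rng = substream(seed, "names")
    rows = []
    for sp in pool:
        rows.append(
            {"verbatim_name": sp.accepted_name, "accepted_name": sp.accepted_name,
             "identifier": f"lsid:{sp.accepted_name.replace(' ', ':')}", "status": "accepted"}
        )
        rows.append(
            {"verbatim_name": sp.accepted_name + " auct.", "accepted_name": sp.accepted_name,
             "identifier": "", "status": "synonym"}
        )
        rows.append(
            {"verbatim_name": _misspell(sp.accepted_name, rng), "accepted_name": sp.accepted_name,
             "identifier": "", "status": "misspelling"}
        )
    for j in range(n_unresolved):
        rows.append(
            {"verbatim_name": f"Dubium nomen{j + 1:03d}", "accepted_name": "",
             "identifier": "", "status": "unresolved"}
        )
    df = pd.DataFrame(rows).drop_duplicates(subset="verbatim_name", keep="first")
    return NameResolutionTable(df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# Occurrence sampling


def _suitability_matrix(
    pool: list[SyntheticSpecies], anmt: GridRaster, anp: GridRaster
) -> np.ndarray:
    """(n_species, n_cells) product-Gaussian niche suitability, zero outside range."""
    cx, cy = anmt.cell_centers()
    cx, cy = cx.reshape(-1), cy.reshape(-1)
    t = anmt.flat()
    p = anp.flat()
    S = np.empty((len(pool), t.size))
    for i, sp in enumerate(pool):
        st, sp_ = sp.niche_breadth
        g = np.exp(-0.5 * ((t - sp.niche_center[0]) / st) ** 2) * np.exp(
            -0.5 * ((p - sp.niche_center[1]) / sp_) ** 2
        )
        d2 = (cx - sp.range_center[0]) ** 2 + (cy - sp.range_center[1]) ** 2
        g[d2 > sp.range_radius_m**2] = 0.0
        S[i] = g
    # point endemics live in exactly one cell: the most suitable one
    for i, sp in enumerate(pool):
        if sp.is_point_endemic:
            row = S[i]
            if row.max() <= 0:
                # fall back to the most climatically suitable cell ignoring range
                st, spb = sp.niche_breadth
                clim = np.exp(-0.5 * ((t - sp.niche_center[0]) / st) ** 2) * np.exp(
                    -0.5 * ((p - sp.niche_center[1]) / spb) ** 2
                )
                home = int(np.argmax(clim))
                S[i] = 0.0
                S[i, home] = max(clim[home], 1e-12)
            else:
                home = int(np.argmax(row))
                keep = row[home]
                S[i] = 0.0
                S[i, home] = keep
    return S


@dataclass
class CorruptionRates:
    """Per-record probabilities of verbatim-name and coordinate corruption."""

    synonym: float = 0.10
    misspelling: float = 0.02
    unresolvable: float = 0.01
    coord_zero: float = 0.005
    coord_missing: float = 0.005
    coord_out_of_range: float = 0.003


def sample_occurrences(
    pool: list[SyntheticSpecies],
    anmt: GridRaster,
    anp: GridRaster,
    effort: EffortSurface,
    n_records: int,
    seed: int,
    name_table: NameResolutionTable | None = None,
    rates: CorruptionRates | None = None,
    projection=SOUTH_AMERICA_LCC,
) -> tuple[pd.DataFrame, dict]:
    """Draw a raw occurrence table and the generator's bookkeeping.

    Each record: (i) a cell drawn from the effort surface (restricted to
    cells where some species is suitable), (ii) a species drawn with
    probability proportional to suitability at that cell, (iii) coordinates
    jittered uniformly within the cell and mapped to WGS84 lon/lat.  Point
    endemics are always emitted at their single fixed locality.  If a name
    table is given, verbatim names are corrupted at the configured rates;
    coordinate corruption never touches point endemics (their single-locality
    structure is part of the design).

    Returns (records, truth) where truth holds the corruption counts and the
    true per-record accepted names.
    """
    if not pool:
        raise SamplingError("empty species pool")
    if n_records < 0:
        raise ValueError("n_records must be non-negative")
    rng = substream(seed, "occurrences")
    rates = rates or CorruptionRates()
    proj = get_projection(projection)

    S = _suitability_matrix(pool, anmt, anp)
    col_tot = S.sum(axis=0)
    pcell = effort.weights * (col_tot > 0)
    if pcell.sum() <= 0:
        raise SamplingError("no cell has both positive effort and positive suitability")
    pcell = pcell / pcell.sum()

    n_cols = anmt.n_cols
    cells = rng.choice(S.shape[1], size=n_records, p=pcell)
    species_idx = np.empty(n_records, dtype=int)
    for c in np.unique(cells):
        sel = cells == c
        pspec = S[:, c] / col_tot[c]
        species_idx[sel] = rng.choice(len(pool), size=int(sel.sum()), p=pspec)

    # coordinates: uniform jitter within the cell; endemics get one fixed locality
    u = rng.random(n_records)
    v = rng.random(n_records)
    endemic_jitter = {
        i: (rng.random(), rng.random()) for i, sp in enumerate(pool) if sp.is_point_endemic
    }
    rows = cells // n_cols
    cols = cells % n_cols
    for k in range(n_records):
        si = species_idx[k]
        if si in endemic_jitter:
            u[k], v[k] = endemic_jitter[si]
    x0, y0 = anmt.origin
    x = x0 + (cols + u) * anmt.cell_size
    y = y0 + (rows + v) * anmt.cell_size
    lon, lat = proj.inverse(x, y)

    accepted = np.array([pool[i].accepted_name for i in species_idx])
    families = np.array([pool[i].family for i in species_idx])
    endemic_mask = np.array([pool[i].is_point_endemic for i in species_idx])

    verbatim = accepted.copy()
    counts = {k: 0 for k in ("synonym", "misspelling", "unresolvable",
                             "coord_zero", "coord_missing", "coord_out_of_range")}
    if name_table is not None and n_records > 0:
        lut = name_table.table
        syn = lut[lut["status"] == "synonym"].set_index("accepted_name")["verbatim_name"]
        mis = lut[lut["status"] == "misspelling"].set_index("accepted_name")["verbatim_name"]
        junk = lut.loc[lut["status"] == "unresolved", "verbatim_name"].to_numpy()
        r = rng.random(n_records)
        p1, p2, p3 = rates.synonym, rates.misspelling, rates.unresolvable
        junk_mask = np.zeros(n_records, dtype=bool)
        for k in range(n_records):
            if r[k] < p1 and accepted[k] in syn.index:
                verbatim[k] = syn.loc[accepted[k]]
                counts["synonym"] += 1
            elif r[k] < p1 + p2 and accepted[k] in mis.index:
                verbatim[k] = mis.loc[accepted[k]]
                counts["misspelling"] += 1
            elif r[k] < p1 + p2 + p3 and len(junk):
                verbatim[k] = junk[rng.integers(len(junk))]
                junk_mask[k] = True
                counts["unresolvable"] += 1
    else:
        junk_mask = np.zeros(n_records, dtype=bool)

    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if n_records > 0:
        rc = rng.random(n_records)
        q1, q2, q3 = rates.coord_zero, rates.coord_missing, rates.coord_out_of_range
        for k in range(n_records):
            if endemic_mask[k] or junk_mask[k]:
                # endemics keep their single-locality structure; records with
                # unresolvable names never reach the coordinate cleaner, so
                # corrupting them would break the generator's bookkeeping
                continue
            if rc[k] < q1:
                lat[k], lon[k] = 0.0, 0.0
                counts["coord_zero"] += 1
            elif rc[k] < q1 + q2:
                lat[k] = np.nan
                counts["coord_missing"] += 1
            elif rc[k] < q1 + q2 + q3:
                lat[k] = 95.0 + 10 * rng.random()
                counts["coord_out_of_range"] += 1

    records = pd.DataFrame(
        {
            "verbatim_name": verbatim,
            "family": families,
            "lat": lat,
            "lon": lon,
            "dataset_id": "synthetic",
        }
    )
    truth = {
        "corruption_counts": counts,
        "true_accepted_name": accepted,
        "cell_index": cells,
        "n_records": int(n_records),
    }
    return records, truth


# ---------------------------------------------------------------------------
# One-call dataset bundle


@dataclass
class SyntheticDataset:
    config: LandscapeConfig
    anmt: GridRaster
    anp: GridRaster
    biome: GridRaster
    region: GridRaster
    transformed: GridRaster
    pool: list[SyntheticSpecies]
    name_table: NameResolutionTable
    use_table: UseTable
    records: pd.DataFrame
    truth: dict

    def write(self, outdir: str | Path) -> None:
        """Write the whole dataset as plain-text artifacts plus a JSON manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, rast in [
            ("anmt", self.anmt), ("anp", self.anp), ("biome", self.biome),
            ("region", self.region), ("transformed", self.transformed),
        ]:
            write_ascii_grid(rast, outdir / f"{name}.asc")
        out = self.records.rename(
            columns={"verbatim_name": "scientificName", "lat": "decimalLatitude",
                     "lon": "decimalLongitude", "dataset_id": "datasetID"}
        )
        out.to_csv(outdir / "occurrences.csv", index=False)
        self.name_table.to_csv(outdir / "name_table.csv")
        self.use_table.to_csv(outdir / "use_table.csv")
        pool_to_frame(self.pool).to_csv(outdir / "species_pool.csv", index=False)
        manifest = {
            "config": asdict(self.config),
            "n_species": len(self.pool),
            "n_records": int(len(self.records)),
            "corruption_counts": self.truth["corruption_counts"],
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def simulate_dataset(
    config: LandscapeConfig,
    n_species: int = 2000,
    n_records: int = 50_000,
    effort: EffortSurface | str = "biased",
    useful_fraction: float = DEFAULT_USEFUL_FRACTION,
    use_marginals: dict[str, float] | None = None,
    endemic_fraction: float = DEFAULT_ENDEMIC_FRACTION,
    rates: CorruptionRates | None = None,
) -> SyntheticDataset:
    """Generate the full synthetic study system from one config."""
    anmt, anp = generate_climate(config)
    biome, region, transformed = generate_layers(config, anmt, anp)
    pool = generate_species_pool(
        config, n_species=n_species, useful_fraction=useful_fraction,
        use_marginals=use_marginals, endemic_fraction=endemic_fraction,
    )
    name_table = build_name_table(pool, config.seed)
    use_table = build_use_table(pool)
    if isinstance(effort, str):
        effort = (
            EffortSurface.uniform(config)
            if effort == "uniform"
            else EffortSurface.access_biased(config)
        )
    records, truth = sample_occurrences(
        pool, anmt, anp, effort, n_records, config.seed,
        name_table=name_table, rates=rates,
    )
    return SyntheticDataset(
        config=config, anmt=anmt, anp=anp, biome=biome, region=region,
        transformed=transformed, pool=pool, name_table=name_table,
        use_table=use_table, records=records, truth=truth,
    )


def default_definition_table(
    config: LandscapeConfig, max_units: int = 13
) -> pd.DataFrame:
    """Definition table for the biome x region overlay.

    Each combination gets its own analysis unit, except that combinations
    beyond ``max_units`` are merged into the last unit (the overlay table is
    many-to-one by design), keeping unit ids clear of the reserved
    transformed-areas id.  With the 5-biome x 3-region default this yields 13
    units, the transformed mask adding the 14th.
    """
    rows = []
    k = 0
    for b in range(1, config.n_biomes + 1):
        for r in range(1, config.n_regions + 1):
            k += 1
            uid = min(k, max_units)
            rows.append(
                {"biome_id": b, "region_id": r, "unit_id": uid,
                 "unit_name": f"biome{b}-region{r}" if k <= max_units
                 else f"merged-unit{max_units}"}
            )
    return pd.DataFrame(rows)
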