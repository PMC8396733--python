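"""Occurrence-record ingest, name resolution, coordinate cleaning, dedup and use attachment.

Records are held in a pandas DataFrame with canonical columns::

    verbatim_name, accepted_name, family, lat, lon, dataset_id, flags

``flags`` is a ``|``-joined sorted string of cleaning-rule identifiers (empty
when clean).  On disk the tables use Darwin-Core-style headers
(``scientificName``, ``decimalLatitude`` ...); :func:`read_occurrences` and
:func:`write_occurrences` translate.

Cleaning follows a documented six-rule subset of the checks coordinate-
cleaning tools apply to biodiversity data: missing/unparseable coordinates,
out-of-range coordinates, the (0, 0) artefact, exactly equal lat/lon
(a common column-duplication error), points outside the country polygon, and
points within a buffer of administrative centroids (a common georeferencing
default).  The unit of analysis downstream is the *unique observation*: one
record per (species, rounded coordinate) after cleaning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

try:  # shapely is only needed when a country polygon is supplied
    from shapely.geometry import Point
    from shapely.prepared import prep
except ImportError:  # pragma: no cover
    Point = None

logger = logging.getLogger(__name__)

#: Closed vocabulary of use categories.
USE_CATEGORIES = (
    "ANIMAL FOOD",
    "ENVIRONMENTAL USES",
    "FUELS",
    "GENE SOURCES",
    "HUMAN FOOD",
    "INVERTEBRATE FOOD",
    "MATERIALS",
    "MEDICINES",
    "POISONS",
    "SOCIAL USES",
)

RECORD_COLUMNS = ["verbatim_name", "accepted_name", "family", "lat", "lon", "dataset_id", "flags"]

#: Darwin-Core-style header <-> canonical column names.
DWC_COLUMN_MAP = {
    "scientificName": "verbatim_name",
    "family": "family",
    "decimalLatitude": "lat",
    "decimalLongitude": "lon",
    "datasetID": "dataset_id",
}

CLEANING_RULES = (
    "coord_missing",
    "coord_out_of_range",
    "zero_zero",
    "equal_lat_lon",
    "outside_country",
    "near_centroid",
)


class SchemaError(ValueError):
    """A mandatory column is missing from an input table."""


def _join_flags(flagsets: list[set[str]]) -> list[str]:
    return ["|".join(sorted(s)) if s else "" for s in flagsets]


def _add_flag(records: pd.DataFrame, mask: np.ndarray, flag: str) -> None:
    cur = records.loc[mask, "flags"]
    records.loc[mask, "flags"] = [
        "|".join(sorted(set(c.split("|")) - {""} | {flag})) for c in cur
    ]


# ---------------------------------------------------------------------------
# Reading / writing


def read_occurrences(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a delimited occurrence table into the canonical record frame.

    Parameters
    ----------
    path : path to a CSV file with a header row.
    column_map : mapping of file column name -> canonical name; defaults to
        the Darwin-Core-style mapping.  Mapped coordinate columns that fail to
        parse as numbers are kept with a ``coord_missing`` flag rather than
        dropped.
    """
    column_map = dict(column_map or DWC_COLUMN_MAP)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in column_map if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s) {missing} in {path}")
    df = raw[list(column_map)].rename(columns=column_map)
    records = pd.DataFrame(
        {
            "verbatim_name": df["verbatim_name"],
            "accepted_name": "",
            "family": df.get("family", ""),
            "lat": pd.to_numeric(df["lat"], errors="coerce"),
            "lon": pd.to_numeric(df["lon"], errors="coerce"),
            "dataset_id": df.get("dataset_id", ""),
            "flags": "",
        }
    )
    bad = records["lat"].isna() | records["lon"].isna()
    _add_flag(records, bad.to_numpy(), "coord_missing")
    return records


def write_occurrences(records: pd.DataFrame, path: str | Path) -> None:
    """Write records with Darwin-Core-style headers (CSV)."""
    inv = {v: k for k, v in DWC_COLUMN_MAP.items()}
    inv["accepted_name"] = "acceptedName"
    out = records.rename(columns=inv)
    order = ["scientificName", "acceptedName", "family", "decimalLatitude",
             "decimalLongitude", "datasetID", "flags"]
    out.to_csv(path, index=False, columns=[c for c in order if c in out.columns])


# ---------------------------------------------------------------------------
# Name resolution


class NameResolutionTable:
    """Verbatim name -> accepted name lookup with nomenclatural status.

    Rows: (verbatim_name, accepted_name, identifier, status) with status in
    {accepted, synonym, misspelling, illegitimate, unresolved}.  Illegitimate
    and unresolved rows carry no accepted name.
    """

    STATUSES = ("accepted", "synonym", "misspelling", "illegitimate", "unresolved")

    def __init__(self, table: pd.DataFrame):
        required = {"verbatim_name", "accepted_name", "status"}
        if not required.issubset(table.columns):
            raise SchemaError(f"resolution table needs columns {sorted(required)}")
        bad_status = set(table["status"]) - set(self.STATUSES)
        if bad_status:
            raise ValueError(f"unknown name status(es): {sorted(bad_status)}")
        if table["verbatim_name"].duplicated().any():
            dupes = table.loc[table["verbatim_name"].duplicated(), "verbatim_name"]
            raise ValueError(f"duplicate verbatim names in resolution table: {list(dupes[:5])}")
        dead = table["status"].isin(["illegitimate", "unresolved"])
        if (table.loc[dead, "accepted_name"].fillna("") != "").any():
            raise ValueError("illegitimate/unresolved rows must not carry an accepted name")
        self.table = table.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path: str | Path) -> "NameResolutionTable":
        return cls(pd.read_csv(path, dtype=str, keep_default_na=False))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def lookup(self) -> pd.DataFrame:
        return self.table.set_index("verbatim_name")


def resolve_names(
    records: pd.DataFrame,
    table: NameResolutionTable,
    policy: str = "discard",
) -> pd.DataFrame:
    """Fill ``accepted_name`` from the resolution table.

    Illegitimate and unresolved names are always discarded.  Names absent from
    the table are handled per ``policy``: ``"discard"`` (default, mirroring a
    strict mismatched-names-are-dropped workflow) or ``"keep"`` (retained with
    an ``unmatched_name`` flag and verbatim name as accepted name).

    The per-outcome counts are logged and stored in
    ``result.attrs["resolution_report"]``.
    """
    if policy not in ("discard", "keep"):
        raise ValueError("policy must be 'discard' or 'keep'")
    lut = table.lookup()
    status = records["verbatim_name"].map(lut["status"])
    accepted = records["verbatim_name"].map(lut["accepted_name"])

    matched = status.isin(["accepted", "synonym", "misspelling"])
    dead = status.isin(["illegitimate", "unresolved"])
    unmatched = status.isna()

    out = records.copy()
    out.loc[matched, "accepted_name"] = accepted[matched]
    keep = matched.copy()
    if policy == "keep":
        out.loc[unmatched, "accepted_name"] = out.loc[unmatched, "verbatim_name"]
        _add_flag(out, unmatched.to_numpy(), "unmatched_name")
        keep |= unmatched
    report = {
        "input": int(len(records)),
        "matched": int(matched.sum()),
        "discarded_illegitimate_or_unresolved": int(dead.sum()),
        "unmatched": int(unmatched.sum()),
        "unmatched_policy": policy,
        "kept": int(keep.sum()),
    }
    logger.info("name resolution: %s", report)
    result = out[keep].reset_index(drop=True)
    result.attrs["resolution_report"] = report
    return result


# ---------------------------------------------------------------------------
# Coordinate cleaning


@dataclass
class CleaningReport:
    """Per-rule removal counts; a record failing several rules counts once in `removed`."""

    input: int = 0
    kept: int = 0
    removed: int = 0
    by_rule: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "input": self.input,
            "kept": self.kept,
            "removed": self.removed,
            "by_rule": dict(self.by_rule),
        }


def clean_coordinates(
    records: pd.DataFrame,
    rules: list[str] | None = None,
    country_polygon=None,
    centroids: list[tuple[float, float]] | None = None,
    radius_km: float = 5.0,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply coordinate-cleaning rules; return (kept records, report).

    ``rules`` defaults to every rule whose reference data is available:
    the four intrinsic rules always, ``outside_country`` when a polygon is
    supplied and ``near_centroid`` when a centroid list is supplied.
    Records failing any enabled rule are removed; each enabled rule's hit
    count is reported independently (a record may hit several rules).
    """
    if rules is None:
        rules = ["coord_missing", "coord_out_of_range", "zero_zero", "equal_lat_lon"]
        if country_polygon is not None:
            rules.append("outside_country")
        if centroids:
            rules.append("near_centroid")
    unknown = set(rules) - set(CLEANING_RULES)
    if unknown:
        raise ValueError(f"unknown cleaning rule(s): {sorted(unknown)}")
    if not rules:
        logger.warning("clean_coordinates called with no rules: passing all records through")
        return records.reset_index(drop=True), CleaningReport(
            input=len(records), kept=len(records), removed=0, by_rule={}
        )

    lat = records["lat"].to_numpy(dtype=float)
    lon = records["lon"].to_numpy(dtype=float)
    hits: dict[str, np.ndarray] = {}

    if "coord_missing" in rules:
        hits["coord_missing"] = np.isnan(lat) | np.isnan(lon)
    finite = ~(np.isnan(lat) | np.isnan(lon))
    if "coord_out_of_range" in rules:
        hits["coord_out_of_range"] = finite & (
            (np.abs(lat) > 90) | (np.abs(lon) > 180)
        )
    if "zero_zero" in rules:
        hits["zero_zero"] = finite & (lat == 0.0) & (lon == 0.0)
    if "equal_lat_lon" in rules:
        hits["equal_lat_lon"] = finite & (lat == lon) & ~((lat == 0.0) & (lon == 0.0))
    if "outside_country" in rules:
        if country_polygon is None:
            raise ValueError("outside_country rule enabled but no polygon supplied")
        prepared = prep(country_polygon)
        out_mask = np.zeros(len(records), dtype=bool)
        for i in np.nonzero(finite)[0]:
            # boundary counts as inside
            p = Point(lon[i], lat[i])
            if not (prepared.contains(p) or country_polygon.touches(p)):
                out_mask[i] = True
        hits["outside_country"] = out_mask
    if "near_centroid" in rules:
        if not centroids:
            raise ValueError("near_centroid rule enabled but no centroid list supplied")
        cen = np.asarray(centroids, dtype=float)  # rows (lat, lon)
        near = np.zeros(len(records), dtype=bool)
        for clat, clon in cen:
            d = _haversine_km(lat, lon, clat, clon)
            near |= finite & (d <= radius_km)
        hits["near_centroid"] = near

    removed_any = np.zeros(len(records), dtype=bool)
    flagged = records.copy()
    for rule, mask in hits.items():
        _add_flag(flagged, mask, rule)
        removed_any |= mask
    report = CleaningReport(
        input=len(records),
        kept=int((~removed_any).sum()),
        removed=int(removed_any.sum()),
        by_rule={rule: int(mask.sum()) for rule, mask in hits.items()},
    )
    logger.info("coordinate cleaning: %s", report.to_dict())
    return flagged[~removed_any].reset_index(drop=True), report


def _haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km (spherical Earth)."""
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = np.sin((la2 - la1) / 2) ** 2 + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2
    return 2 * 6371.0 * np.arcsin(np.sqrt(a))


# ---------------------------------------------------------------------------
# Deduplication


def deduplicate(records: pd.DataFrame, precision_decimals: int = 4) -> pd.DataFrame:
    """Collapse to unique observations: one record per (accepted_name, rounded lat, rounded lon).

    Records are stably sorted on (accepted_name, lat, lon, dataset_id) and the
    first of each duplicate group is kept, so the result is deterministic and
    independent of input order.  4 decimals (~11 m) is the default locality
    precision.
    """
    key_lat = records["lat"].round(precision_decimals)
    key_lon = records["lon"].round(precision_decimals)
    tmp = records.assign(_klat=key_lat, _klon=key_lon)
    tmp = tmp.sort_values(
        ["accepted_name", "lat", "lon", "dataset_id"], kind="mergesort"
    )
    tmp = tmp.drop_duplicates(subset=["accepted_name", "_klat", "_klon"], keep="first")
    return tmp.drop(columns=["_klat", "_klon"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Use categories


class UseTable:
    """Species -> use-category table over the closed 10-category vocabulary."""

    def __init__(self, table: pd.DataFrame):
        required = {"accepted_name", "category"}
        if not required.issubset(table.columns):
            raise SchemaError(f"use table needs columns {sorted(required)}")
        bad = set(table["category"]) - set(USE_CATEGORIES)
        if bad:
            raise ValueError(f"use categories outside the vocabulary: {sorted(bad)}")
        self.table = table.drop_duplicates().reset_index(drop=True)

    @classmethod
    def from_csv(cls, path: str | Path) -> "UseTable":
        return cls(pd.read_csv(path, dtype=str, keep_default_na=False))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def species_uses(self) -> dict[str, frozenset]:
        return {
            name: frozenset(grp["category"])
            for name, grp in self.table.groupby("accepted_name")
        }


def attach_uses(records: pd.DataFrame, use_table: UseTable) -> pd.DataFrame:
    """Attach the multi-category use set to each record.

    Adds ``uses`` (frozenset, empty when not useful) and ``is_useful``.
    A species is useful iff its accepted name appears in the use table; a
    multi-use species keeps its whole category set on every record.
    """
    lut = use_table.species_uses()
    out = records.copy()
    out["uses"] = out["accepted_name"].map(lambda n: lut.get(n, frozenset()))
    out["is_useful"] = out["uses"].map(bool)
    return out
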