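"""Use-category statistics, the bioregion x use record matrix, and its clustering.

A species (or record) counts once in every category it holds, so category
species and record counts deliberately exceed the useful totals — the
percentages are shares of the useful totals, not a partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .occurrences import USE_CATEGORIES


def category_stats_from_counts(
    counts: pd.DataFrame, total_species: int, total_records: int
) -> pd.DataFrame:
    """Derive percentages and records:species ratios from per-category counts.

    ``counts`` has index = category and columns ``n_species``, ``n_records``.
    Percentages are taken against the useful-species and useful-record
    totals; the ratio is records/species (NaN for empty categories).  All
    derived columns are rounded to 2 dp, the convention of the source
    tabulation.
    """
    out = counts.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        out["pct_of_useful_species"] = (100.0 * out["n_species"] / total_species).round(2)
        out["pct_of_useful_records"] = (100.0 * out["n_records"] / total_records).round(2)
        ratio = out["n_records"] / out["n_species"].replace(0, np.nan)
    out["records_species_ratio"] = ratio.round(2)
    return out[
        ["n_species", "pct_of_useful_species", "n_records",
         "pct_of_useful_records", "records_species_ratio"]
    ]


def category_totals(records: pd.DataFrame) -> pd.DataFrame:
    """Per-category species/record counts, percentages and ratios.

    ``records`` must carry ``accepted_name``, ``uses`` (frozensets) and
    ``is_useful``.  Only useful records enter; each counts once per category
    it holds.  Rows are ordered by descending species count (ties
    alphabetical).
    """
    useful = records[records["is_useful"]]
    total_species = useful["accepted_name"].nunique()
    total_records = len(useful)
    exploded = useful[["accepted_name", "uses"]].explode("uses").rename(
        columns={"uses": "category"}
    )
    counts = (
        exploded.groupby("category")
        .agg(n_species=("accepted_name", "nunique"), n_records=("accepted_name", "size"))
        .reindex(sorted(set(exploded["category"].dropna())), fill_value=0)
    )
    stats = category_stats_from_counts(counts, total_species, total_records)
    stats.attrs["total_species"] = int(total_species)
    stats.attrs["total_records"] = int(total_records)
    ordered = stats.sort_index().sort_values("n_species", ascending=False, kind="mergesort")
    ordered.attrs = stats.attrs
    return ordered


def bioregion_use_matrix(records: pd.DataFrame, unit_ids=None) -> pd.DataFrame:
    """units x categories matrix of useful-record counts.

    Entry (u, c) is the number of useful records in unit u carrying category
    c; a multi-use record counts in every category it holds, so a row sums to
    more than the unit's useful-record count when uses overlap.
    """
    useful = records[records["is_useful"] & (records["unit"] >= 0)]
    exploded = useful[["unit", "uses"]].explode("uses").rename(columns={"uses": "category"})
    mat = (
        exploded.groupby(["unit", "category"]).size().unstack(fill_value=0)
    )
    cats = [c for c in USE_CATEGORIES if c in mat.columns] + [
        c for c in mat.columns if c not in USE_CATEGORIES
    ]
    mat = mat[cats]
    if unit_ids is not None:
        mat = mat.reindex(sorted(unit_ids), fill_value=0)
    return mat.astype(int)


@dataclass
class ClusterResult:
    """Leaf orders and linkage trees of the clustered count matrix."""

    row_order: list
    col_order: list
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None
    transformed: pd.DataFrame


def _axis_linkage(data: np.ndarray, method: str, metric: str):
    if data.shape[0] < 2:
        return None, [0] if data.shape[0] else []
    d = pdist(data, metric=metric)
    Z = hierarchy.linkage(d, method=method)
    order = hierarchy.leaves_list(Z).tolist()
    return Z, order


def cluster_matrix(
    matrix: pd.DataFrame,
    method: str = "average",
    metric: str = "euclidean",
    log_transform: bool = True,
) -> ClusterResult:
    """Agglomerative clustering of rows and columns of the count matrix.

    By default distances are Euclidean on log10(count + 1) (the offset admits
    zeros), with average linkage — robust to the order-of-magnitude spread of
    record counts.  Deterministic given scipy's tie-break (input order), and
    invariant to row/column permutation up to the corresponding relabelling.
    """
    if matrix.size == 0:
        raise ValueError("cannot cluster an empty matrix")
    data = matrix.to_numpy(dtype=float)
    if log_transform:
        data = np.log10(data + 1.0)
    tdf = pd.DataFrame(data, index=matrix.index, columns=matrix.columns)
    row_Z, row_ord = _axis_linkage(data, method, metric)
    col_Z, col_ord = _axis_linkage(data.T, method, metric)
    return ClusterResult(
        row_order=[matrix.index[i] for i in row_ord],
        col_order=[matrix.columns[i] for i in col_ord],
        row_linkage=row_Z,
        col_linkage=col_Z,
        transformed=tdf,
    )


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick tree with branch lengths."""
    if Z is None:
        return f"({labels[0]});" if len(labels) == 1 else ";"
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def top_families(species_table: pd.DataFrame, n: int | None = None) -> pd.DataFrame:
    """Families ranked by number of useful species (descending, ties alphabetical).

    ``species_table`` has one row per species with columns ``accepted_name``,
    ``family`` and ``is_useful`` (or pass a pre-filtered useful table without
    the flag).
    """
    tab = species_table
    if "is_useful" in tab.columns:
        tab = tab[tab["is_useful"]]
    counts = (
        tab.drop_duplicates("accepted_name")
        .groupby("family")
        .size()
        .rename("n_useful_species")
        .reset_index()
        .sort_values(["n_useful_species", "family"], ascending=[False, True],
                     kind="mergesort")
        .reset_index(drop=True)
    )
    return counts.head(n) if n else counts
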