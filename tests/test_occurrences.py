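"""Ingest, name resolution, cleaning rules, dedup and use attachment."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from floragap.occurrences import (
    CleaningReport,
    NameResolutionTable,
    SchemaError,
    UseTable,
    attach_uses,
    clean_coordinates,
    deduplicate,
    read_occurrences,
    resolve_names,
)
from conftest import make_records


class TestReadOccurrences:
    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "e.csv"
        p.write_text("scientificName,family,decimalLatitude,decimalLongitude,datasetID\n")
        assert len(read_occurrences(p)) == 0

    def test_unparseable_coordinate_flagged_not_dropped(self, tmp_path):
        p = tmp_path / "b.csv"
        p.write_text(
            "scientificName,family,decimalLatitude,decimalLongitude,datasetID\n"
            "Aa bb,F,abc,-70.1,d1\n"
        )
        recs = read_occurrences(p)
        assert len(recs) == 1
        assert "coord_missing" in recs.loc[0, "flags"]

    def test_three_rows_match_hand_parse(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "scientificName,family,decimalLatitude,decimalLongitude,datasetID\n"
            "Aa bb,Fab,4.5,-70.25,d1\n"
            "Cc dd,Fcd,-1.25,-66.0,d2\n"
            "Ee ff,Fef,10.0,-75.5,d1\n"
        )
        recs = read_occurrences(p)
        assert list(recs["verbatim_name"]) == ["Aa bb", "Cc dd", "Ee ff"]
        assert list(recs["family"]) == ["Fab", "Fcd", "Fef"]
        assert list(recs["lat"]) == [4.5, -1.25, 10.0]
        assert list(recs["lon"]) == [-70.25, -66.0, -75.5]
        assert list(recs["dataset_id"]) == ["d1", "d2", "d1"]

    def test_missing_column_names_it(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("scientificName,decimalLatitude\nAa bb,4.5\n")
        with pytest.raises(SchemaError, match="decimalLongitude"):
            read_occurrences(p)


@pytest.fixture
def name_table():
    return NameResolutionTable(pd.DataFrame(
        [
            ("Aa bb", "Aa bb", "accepted"),
            ("Cc dd", "Cc dd", "accepted"),
            ("Ee ff", "Ee ff", "accepted"),
            ("Aa bbb", "Aa bb", "synonym"),
            ("Cc de", "Cc dd", "synonym"),
            ("E ff", "Ee ff", "misspelling"),
            ("Xx yy", "", "unresolved"),
            ("Zz ww", "", "illegitimate"),
        ],
        columns=["verbatim_name", "accepted_name", "status"],
    ))


class TestResolveNames:
    def test_accepted_name_identity(self, name_table):
        recs = make_records([("Aa bb", 1.0, 2.0)])
        out = resolve_names(recs, name_table)
        assert out.loc[0, "accepted_name"] == "Aa bb"

    def test_synonym_mapped(self, name_table):
        recs = make_records([("Aa bbb", 1.0, 2.0)])
        out = resolve_names(recs, name_table)
        assert out.loc[0, "accepted_name"] == "Aa bb"

    def test_ten_name_fixture_manual_walk(self, name_table):
        # 5 accepted/synonym/misspelling hits, 2 dead names, 3 repeats of hits
        names = ["Aa bb", "Aa bbb", "Cc dd", "Cc de", "E ff",
                 "Xx yy", "Zz ww", "Aa bb", "Cc dd", "Ee ff"]
        recs = make_records([(n, 1.0, 2.0) for n in names])
        out = resolve_names(recs, name_table, policy="discard")
        # manual walk: all except Xx yy (unresolved) and Zz ww (illegitimate)
        assert len(out) == 8
        assert out.attrs["resolution_report"]["discarded_illegitimate_or_unresolved"] == 2

    def test_keep_policy_flags_unmatched(self, name_table):
        recs = make_records([("Qq rr", 1.0, 2.0)])
        out = resolve_names(recs, name_table, policy="keep")
        assert len(out) == 1
        assert "unmatched_name" in out.loc[0, "flags"]
        assert len(resolve_names(recs, name_table, policy="discard")) == 0

    def test_table_validation(self):
        with pytest.raises(ValueError, match="accepted name"):
            NameResolutionTable(pd.DataFrame(
                [("Xx yy", "Aa bb", "unresolved")],
                columns=["verbatim_name", "accepted_name", "status"],
            ))


class TestCleanCoordinates:
    def test_zero_zero_removed(self):
        kept, rep = clean_coordinates(make_records([("A a", 0.0, 0.0)]))
        assert len(kept) == 0 and rep.by_rule["zero_zero"] == 1

    def test_equal_lat_lon_removed(self):
        kept, rep = clean_coordinates(make_records([("A a", 4.5, 4.5)]))
        assert len(kept) == 0 and rep.by_rule["equal_lat_lon"] == 1

    def test_out_of_range_removed(self):
        kept, rep = clean_coordinates(make_records([("A a", 95.0, -70.0)]))
        assert rep.by_rule["coord_out_of_range"] == 1 and len(kept) == 0

    def test_polygon_rule_matches_brute_force(self):
        square = Polygon([(-75, 0), (-65, 0), (-65, 10), (-75, 10)])
        rng = np.random.default_rng(7)
        lon = rng.uniform(-80, -60, 20)
        lat = rng.uniform(-5, 15, 20)
        recs = make_records([(f"S {i}", lat[i], lon[i]) for i in range(20)])
        kept, rep = clean_coordinates(
            recs, rules=["outside_country"], country_polygon=square
        )
        inside = [(-75 <= lon[i] <= -65) and (0 <= lat[i] <= 10) for i in range(20)]
        assert len(kept) == sum(inside)
        assert rep.by_rule["outside_country"] == 20 - sum(inside)

    def test_centroid_radius_rule(self):
        recs = make_records([("A a", 4.6, -74.08), ("B b", 6.0, -74.08)])
        kept, rep = clean_coordinates(
            recs, rules=["near_centroid"], centroids=[(4.6, -74.08)], radius_km=5.0
        )
        assert list(kept["verbatim_name"]) == ["B b"]

    def test_empty_rule_set_passes_through(self):
        recs = make_records([("A a", 0.0, 0.0)])
        kept, rep = clean_coordinates(recs, rules=[])
        assert len(kept) == 1 and rep.removed == 0

    def test_partition_conserved(self):
        rng = np.random.default_rng(2)
        rows = [("S", rng.uniform(-100, 100), rng.uniform(-200, 200)) for _ in range(200)]
        kept, rep = clean_coordinates(make_records(rows))
        assert rep.kept + rep.removed == rep.input == 200
        assert len(kept) == rep.kept


class TestDeduplicate:
    def test_exact_duplicates_single_survivor(self):
        recs = make_records([("A a", 1.0, 2.0)] * 3)
        assert len(deduplicate(recs)) == 1

    def test_nearby_points_kept_at_precision_4(self):
        recs = make_records([("A a", 1.0000, 2.0), ("A a", 1.0001, 2.0)])
        assert len(deduplicate(recs, 4)) == 2
        assert len(deduplicate(recs, 3)) == 1

    def test_engineered_collisions_match_set_oracle(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(83):
            rows.append((f"Sp {i % 9}", round(rng.uniform(0, 5), 4), round(rng.uniform(0, 5), 4)))
        # engineer 17 collisions by repeating existing rows
        for j in range(17):
            rows.append(rows[j * 3 % 83])
        recs = make_records(rows)
        oracle = {(n, round(la, 4), round(lo, 4)) for n, la, lo in rows}
        assert len(deduplicate(recs, 4)) == len(oracle) == 83

    def test_order_invariant_and_idempotent(self):
        rng = np.random.default_rng(8)
        rows = [(f"Sp {rng.integers(3)}", round(rng.uniform(0, 1), 4), 2.0)
                for _ in range(50)]
        recs = make_records(rows)
        d1 = deduplicate(recs)
        d2 = deduplicate(recs.sample(frac=1, random_state=1))
        pd.testing.assert_frame_equal(
            d1.reset_index(drop=True), d2.reset_index(drop=True)
        )
        pd.testing.assert_frame_equal(deduplicate(d1), d1)


class TestCleaningDedupIdempotence:
    def test_clean_then_dedup_twice_equals_once(self):
        rng = np.random.default_rng(4)
        rows = [(f"Sp {rng.integers(5)}", rng.uniform(-95, 95), rng.uniform(-100, 100))
                for _ in range(300)]
        recs = make_records(rows)

        def pipeline(r):
            kept, _ = clean_coordinates(r)
            return deduplicate(kept)

        once = pipeline(recs)
        twice = pipeline(once)
        pd.testing.assert_frame_equal(once, twice)


class TestUses:
    def test_absent_species_not_useful(self):
        ut = UseTable(pd.DataFrame([("Aa bb", "MEDICINES")],
                                   columns=["accepted_name", "category"]))
        recs = make_records([("Cc dd", 1.0, 2.0)])
        out = attach_uses(recs, ut)
        assert not out.loc[0, "is_useful"] and out.loc[0, "uses"] == frozenset()

    def test_multi_use_species_counts_in_each_category(self):
        ut = UseTable(pd.DataFrame(
            [("Aa bb", "MEDICINES"), ("Aa bb", "HUMAN FOOD")],
            columns=["accepted_name", "category"],
        ))
        recs = attach_uses(make_records([("Aa bb", 1.0, 2.0)]), ut)
        assert recs.loc[0, "uses"] == frozenset({"MEDICINES", "HUMAN FOOD"})

    def test_category_outside_vocabulary_rejected(self):
        with pytest.raises(ValueError, match="vocabulary"):
            UseTable(pd.DataFrame([("Aa bb", "SPELLS")],
                                  columns=["accepted_name", "category"]))

    def test_record_tallies_match_hand_tally(self):
        # 5 species, 12 records, 3 categories
        ut = UseTable(pd.DataFrame(
            [("S1", "MEDICINES"), ("S1", "HUMAN FOOD"), ("S2", "MEDICINES"),
             ("S3", "FUELS"), ("S4", "HUMAN FOOD")],
            columns=["accepted_name", "category"],
        ))
        counts = {"S1": 3, "S2": 2, "S3": 4, "S4": 2, "S5": 1}
        rows = [(s, 1.0 + i, 2.0) for s, n in counts.items() for i in range(n)]
        recs = attach_uses(make_records(rows), ut)
        per_cat = {}
        for _, r in recs.iterrows():
            for c in r["uses"]:
                per_cat[c] = per_cat.get(c, 0) + 1
        # hand tally: MEDICINES = S1+S2 = 5; HUMAN FOOD = S1+S4 = 5; FUELS = S3 = 4
        assert per_cat == {"MEDICINES": 5, "HUMAN FOOD": 5, "FUELS": 4}
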