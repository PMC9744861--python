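import numpy as np
import pandas as pd
import pytest

from occutrend import prep


def _rec(species, square, date, observer=None, project=None, stage="adult",
         group="butterflies", hint="private"):
    return {"species_id": species, "group": group, "square_id": square,
            "date": pd.Timestamp(date), "observer_id": observer,
            "project_id": project, "source_hint": hint, "life_stage": stage}


@pytest.fixture
def toy_records():
    rows = [
        _rec("s1", "a", "1995-06-01", "o1"),
        _rec("s2", "a", "1995-06-01", "o1"),
        _rec("s3", "a", "1995-06-01", "o1"),
        _rec("s1", "b", "1995-06-01", "o1"),
        _rec("s1", "a", "2001-07-10", "o2"),
        _rec("s2", "a", "2001-07-10", "o2"),
        _rec("s1", "c", "1995-05-05", "o3"),          # square c: one year only
        _rec("s2", "c", "1995-05-06", "o3"),
        _rec("s1", "b", "2002-08-01", "o2", stage="larva"),
        _rec("s3", "b", "2002-08-02", "o2"),
    ]
    return pd.DataFrame(rows)


class TestBuildVisits:
    def test_same_observer_day_square_one_visit(self, toy_records):
        v = prep.build_visits(toy_records.iloc[[0, 1, 2]])
        assert len(v) == 1
        assert v.iloc[0]["n_species_recorded"] == 3
        assert v.iloc[0]["list_length_class"] == "2-3"

    def test_four_species_long_list(self):
        rows = [_rec(f"s{i}", "a", "1999-06-01", "o1") for i in range(4)]
        v = prep.build_visits(pd.DataFrame(rows))
        assert v.iloc[0]["list_length_class"] == ">3"

    def test_two_squares_two_visits(self, toy_records):
        v = prep.build_visits(toy_records.iloc[[0, 3]])
        assert len(v) == 2

    def test_missing_keys_rejected_with_warning(self, caplog):
        rows = [_rec("s1", "a", "1999-06-01", "o1"), _rec("s2", "a", "1999-06-01")]
        with caplog.at_level("WARNING"):
            v = prep.build_visits(pd.DataFrame(rows))
        assert len(v) == 1
        assert "dropping 1 records" in caplog.text

    def test_row_order_invariance(self, toy_records):
        a = prep.build_visits(toy_records)
        b = prep.build_visits(toy_records.sample(frac=1.0, random_state=7))
        cols = ["square_id", "date", "key", "n_species_recorded", "n_records",
                "list_length_class"]
        pd.testing.assert_frame_equal(a[cols].reset_index(drop=True),
                                      b[cols].reset_index(drop=True))


class TestFilterRecords:
    def test_toy_hand_count(self, toy_records):
        # 10 records: 1 larval, 2 in the single-year square c -> 7 survive
        out = prep.filter_records(toy_records, 1980, 2020)
        assert len(out) == 7
        assert "c" not in set(out["square_id"])

    def test_single_year_square_removed_multi_year_kept(self, toy_records):
        out = prep.filter_records(toy_records, 1980, 2020)
        assert {"a", "b"} == set(out["square_id"])  # a: 1995+2001, b: 1995+2002

    def test_warmup_start_per_group(self):
        rows = [_rec("s1", "a", "1975-06-01", "o1"),
                _rec("s1", "a", "1982-06-01", "o1"),
                _rec("g1", "b", "1975-06-01", "o1", group="grasshoppers"),
                _rec("g1", "b", "1982-06-01", "o1", group="grasshoppers"),
                _rec("g1", "b", "1983-06-01", "o1", group="grasshoppers")]
        out = prep.filter_records(pd.DataFrame(rows), 1980, 2020,
                                  warmup_start={"butterflies": 1970})
        # butterflies keep their warm-up decade; grasshoppers lose 1975
        assert len(out[out["group"] == "butterflies"]) == 2
        assert len(out[out["group"] == "grasshoppers"]) == 2

    def test_empty_output_names_filter(self, toy_records):
        larvae = toy_records.assign(life_stage="larva")
        with pytest.raises(ValueError, match="non-adult"):
            prep.filter_records(larvae, 1980, 2020)


class TestSelectSpecies:
    def _records_with_years(self, years):
        return pd.DataFrame([_rec("sp", "a", f"{y}-06-01", "o1") for y in years])

    def test_quarter_threshold_41_years(self):
        analysed = np.arange(1980, 2021)
        assert prep.select_species(self._records_with_years(range(1980, 1990)),
                                   analysed) == []          # 10/41 = 0.244
        assert prep.select_species(self._records_with_years(range(1980, 1991)),
                                   analysed) == ["sp"]      # 11/41 = 0.268

    def test_zero_threshold_keeps_all(self):
        rec = self._records_with_years([1999])
        assert prep.select_species(rec, np.arange(1980, 2021), 0.0) == ["sp"]


class TestClassifyObservers:
    def test_top_observer_with_longest_list_is_expert(self):
        # distinct totals so the 2.5% cut falls strictly inside the range
        rows = [{"visit_id": f"v{i}", "observer_id": f"o{i:02d}", "n_records": i + 1}
                for i in range(40)]
        rows.append({"visit_id": "vstar", "observer_id": "star", "n_records": 200})
        v = pd.DataFrame(rows)
        exp = prep.classify_observers(v)
        assert exp["star"]
        # observers clearly below the record-count cut are never experts
        assert not exp[[f"o{i:02d}" for i in range(30)]].any()

    def test_top_by_records_but_short_visits_not_expert(self):
        rows = []
        vid = 0
        # "busy" has the largest record total but only ever short visits
        for _ in range(60):
            rows.append({"visit_id": f"v{vid}", "observer_id": "busy", "n_records": 1})
            vid += 1
        for i in range(39):
            rows.append({"visit_id": f"v{vid}", "observer_id": f"o{i}",
                         "n_records": 1 + i % 4})
            vid += 1
        rows.append({"visit_id": "c", "observer_id": "sharp", "n_records": 50})
        v = pd.DataFrame(rows)
        exp = prep.classify_observers(v)
        assert not exp["busy"]  # many records, but no exceptionally long list

    def test_matches_brute_force_on_200_observers(self, rng):
        rows = []
        for i in range(200):
            n_vis = int(rng.integers(1, 8))
            for j in range(n_vis):
                rows.append({"visit_id": f"v{i}_{j}", "observer_id": f"o{i:03d}",
                             "n_records": int(rng.integers(1, 30))})
        v = pd.DataFrame(rows)
        got = prep.classify_observers(v)
        totals = v.groupby("observer_id")["n_records"].sum()
        cut_obs = np.quantile(totals, 0.975)
        cut_vis = np.quantile(v["n_records"], 0.975)
        for obs in totals.index:
            expected = (totals[obs] >= cut_obs) and \
                (v.loc[v["observer_id"] == obs, "n_records"] >= cut_vis).any()
            assert got[obs] == expected


class TestDetectionHistories:
    def _world(self):
        squares = pd.DataFrame({"square_id": ["a", "b", "c"],
                                "zone": ["z1", "z1", "z2"]})
        rows = []
        # focal species recorded on days 100..199 in zone z1 only
        for d in range(100, 200, 10):
            rows.append(_rec("sp", "a", f"2000-01-01", "o1"))
            rows[-1]["date"] = pd.Timestamp("2000-01-01") + pd.Timedelta(days=d - 1)
        # another observer visits day 95 (below the 5% record quantile)
        rows.append(_rec("other", "a", "2000-04-04", "o2"))  # day 95
        # a visit in zone z2 where sp was never recorded
        rows.append(_rec("other", "c", "2000-06-01", "o3"))
        # targeted project on a different species
        rows.append(_rec("other", "b", "2000-06-10", None, project="p1",
                         hint="targeted_project"))
        return squares, pd.DataFrame(rows)

    def test_filters_a_b_c(self):
        squares, rec = self._world()
        visits = prep.build_visits(rec)
        projects = pd.DataFrame([{"project_id": "p1", "kind": "targeted_project",
                                  "group": "butterflies",
                                  "target_species": "other"}])
        hist = prep.build_detection_histories(["sp"], visits, rec, squares, projects)
        h = hist["sp"]
        # (b): the day-95 visit removed (below 5% quantile of sp record days),
        # along with the two tail record-days of sp itself (empirical 5%/95%
        # quantiles of days 100..190 are 104.5 and 185.5);
        # (c): the z2 visit removed; (a): the targeted-project visit removed
        assert len(h) == 8
        assert set(h["zone"]) == {"z1"}
        assert h["y"].sum() == 8

    def test_detections_map_one_to_one(self, rng):
        squares = pd.DataFrame({"square_id": ["a", "b"], "zone": ["z1", "z1"]})
        # identical day-of-year keeps the quantile window degenerate (no loss)
        rows = [_rec("sp", "a", f"200{k + 1}-06-15", "o1") for k in range(3)]
        rows += [_rec("bg", "b", f"200{k + 1}-06-15", "o1") for k in range(3)]
        rec = pd.DataFrame(rows)
        visits = prep.build_visits(rec)
        hist = prep.build_detection_histories(["sp"], visits, rec, squares)
        assert hist["sp"]["y"].sum() == 3  # one per input record of sp

    def test_idempotent_reprep(self, toy_records):
        once = prep.filter_records(toy_records, 1980, 2020)
        twice = prep.filter_records(once, 1980, 2020)
        pd.testing.assert_frame_equal(once.reset_index(drop=True),
                                      twice.reset_index(drop=True))
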