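import pandas as pd
import pytest

from windmort.data_io import (
    Dataset,
    FormatError,
    NightRecord,
    ValidationError,
    load_example_year_summary,
    read_detection_table,
    read_night_table,
    summarize_dataset,
    write_detection_table,
    write_night_table,
)

from conftest import make_detection


class TestDetectionTable:
    def test_bundled_table_parses_30_turbines(self, example_detections):
        assert len(example_detections) == 30
        t1 = example_detections[0]
        assert t1.turbine_id == "1" and t1.year == 2007
        assert t1.total_found == 1 and t1.n_searches == 23
        assert t1.fall_in == 0.92
        assert t1.detection_mean == 0.70
        assert t1.detection_ci == (0.50, 0.85)

    def test_point_estimate_outside_printed_ci_is_accepted(
            self, example_detections):
        # turbines 1 and 23 carry persistence CIs excluding the point
        # estimate; only the CI width is consumed, so the rows must load
        t23 = next(d for d in example_detections if d.turbine_id == "23")
        assert t23.persistence_mean == 0.47
        assert t23.persistence_ci == (0.54, 0.94)

    def test_empty_file_is_a_format_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(FormatError):
            read_detection_table(path)

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("turbine,year,C\n1,2007,0\n")
        with pytest.raises(FormatError, match="T"):
            read_detection_table(path)

    def test_probability_outside_unit_interval_rejected(self, tmp_path):
        df = pd.read_csv(
            "src/windmort/data/table2_detection.csv").head(1)
        df["p"] = 1.4
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match=r"row 1"):
            read_detection_table(path)

    def test_round_trip_preserves_full_precision(self, tmp_path):
        records = [
            make_detection(tid="a", C=3, T=45, p=0.7123456789),
            make_detection(tid="b", C=0, T=12, s=0.333333333333),
            make_detection(tid="c", C=9, T=80, f=0.125),
        ]
        path = tmp_path / "dets.csv"
        write_detection_table(records, path)
        assert read_detection_table(path) == records


class TestNightTable:
    def _write(self, tmp_path, rows):
        path = tmp_path / "nights.csv"
        path.write_text("turbine,night,count,activity,wind,searched\n"
                        + "\n".join(rows) + "\n")
        return path

    def test_rows_sorted_by_turbine_and_night(self, tmp_path):
        rows = ["b,2,0,5,4.0,True", "a,1,1,2,3.0,True", "b,1,0,9,6.0,True",
                "a,2,0,1,2.5,True", "a,3,0,0,8.0,True", "b,3,0,3,5.5,True"]
        records = read_night_table(self._write(tmp_path, rows))
        assert len(records) == 6
        assert [(r.turbine_id, r.night_index) for r in records] == [
            ("a", 1), ("a", 2), ("a", 3), ("b", 1), ("b", 2), ("b", 3)]

    def test_gap_in_night_index_rejected(self, tmp_path):
        rows = ["a,1,0,2,3.0,True", "a,3,0,1,2.0,True"]
        with pytest.raises(ValidationError, match="consecutive"):
            read_night_table(self._write(tmp_path, rows))

    def test_carcass_on_unsearched_night_rejected(self, tmp_path):
        rows = ["a,1,1,2,3.0,False"]
        with pytest.raises(ValidationError, match="unsearched"):
            read_night_table(self._write(tmp_path, rows))

    @pytest.mark.parametrize("row,msg", [
        ("a,1,-1,2,3.0,True", "non-negative"),
        ("a,1,0,2,breeze,True", "row 1"),
    ])
    def test_bad_values_reported_with_row_number(self, tmp_path, row, msg):
        with pytest.raises(ValidationError, match=msg):
            read_night_table(self._write(tmp_path, [row]))

    def test_simulated_table_round_trips(self, tmp_path):
        from windmort.simulation import SimConfig, simulate_replicate
        rep = simulate_replicate(SimConfig(n_turbines=3,
                                           nights_per_turbine=15, seed=4))
        path = tmp_path / "sim.csv"
        write_night_table(rep.dataset.nights, path)
        assert read_night_table(path) == sorted(
            rep.dataset.nights, key=lambda r: (r.turbine_id, r.night_index))


class TestDatasetAndSummary:
    def test_night_turbine_must_have_detection_entry(self):
        with pytest.raises(ValidationError, match="missing"):
            Dataset(nights=[NightRecord("x", 1, 0, 0, 1.0)], detections={})

    def test_year_totals_match_published_aggregates(self, example_detections):
        out = summarize_dataset(example_detections).set_index("year")
        assert out.loc[2007, "total_carcasses"] == 22
        assert out.loc[2007, "turbine_nights"] == 473
        assert out.loc[2008, "total_carcasses"] == 35
        assert out.loc[2008, "turbine_nights"] == 1225
        assert round(out.loc[2008, "mean_detection"], 2) == 0.61

    def test_totals_equal_brute_force_sums(self, example_detections):
        out = summarize_dataset(example_detections).set_index("year")
        for year in (2007, 2008):
            sub = [d for d in example_detections if d.year == year]
            assert out.loc[year, "total_carcasses"] == sum(
                d.total_found for d in sub)
            assert out.loc[year, "turbine_nights"] == sum(
                d.n_searches for d in sub)

    def test_single_zero_turbine(self):
        out = summarize_dataset([make_detection(C=0)])
        assert out["total_carcasses"].tolist() == [0]

    def test_year_summary_fixture_is_consistent(self):
        t1 = load_example_year_summary().set_index("year")
        assert t1.loc[2007, "n_nights"] == 473
        assert t1.loc[2008, "n_carcasses"] == 35
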