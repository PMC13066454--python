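import numpy as np
import pandas as pd
import pytest

from phenocurate import (
    SimulationParams,
    read_workbook,
    simulate_dataset,
    validate_dataset,
    write_curated,
)
from phenocurate.miappe_io import FormatError, WorkbookLayout

from conftest import make_dataset


def write_sections(tmp_path, study=None, variables=None, data=None,
                   fmt="xlsx"):
    """Assemble a workbook from raw section tables (defaults are valid)."""
    if study is None:
        study = pd.DataFrame({
            "study_id": ["S1", "S2"],
            "genebank": ["XXX001", "XXX001"],
            "campaign_year": [2001, 2002],
            "location_name": ["site", "site"],
            "latitude": [47.0, 47.0], "longitude": [8.0, 8.0],
            "seasonal_type": ["winter", "winter"],
            "start_date": [None, None], "end_date": [None, None],
        })
    if variables is None:
        variables = pd.DataFrame({
            "code": ["PH"], "label": ["plant height"], "unit": ["cm"],
            "plausible_min": [5], "plausible_max": [250],
            "method_note": [""],
        })
    if data is None:
        data = pd.DataFrame({
            "study_id": ["S1"] * 3 + ["S2"] * 3,
            "institute_code": ["XXX001"] * 6,
            "genus": ["Triticum"] * 6,
            "accession_number": ["A", "B", "C"] * 2,
            "trait": ["PH"] * 6,
            "value": [80.0, 90.0, 100.0, 85.0, 95.0, 105.0],
        })
    if fmt == "xlsx":
        path = tmp_path / "book.xlsx"
        with pd.ExcelWriter(path) as xl:
            study.to_excel(xl, sheet_name="study", index=False)
            variables.to_excel(xl, sheet_name="observation_variables", index=False)
            data.to_excel(xl, sheet_name="data", index=False)
    else:
        path = tmp_path / "book"
        path.mkdir()
        study.to_csv(path / "study.csv", index=False)
        variables.to_csv(path / "variables.csv", index=False)
        data.to_csv(path / "data.csv", index=False)
    return path


class TestReadWorkbook:
    @pytest.mark.parametrize("fmt", ["xlsx", "csv"])
    def test_count_conservation_two_studies(self, tmp_path, fmt):
        ds = read_workbook(write_sections(tmp_path, fmt=fmt))
        assert len(ds.df) == 6
        assert set(ds.traits) == {"PH"}
        assert sorted(ds.df["year"].unique()) == [2001, 2002]
        assert ds.read_log == []

    def test_non_numeric_cell_logged_and_skipped(self, tmp_path):
        data = pd.DataFrame({
            "study_id": ["S1"] * 6, "institute_code": ["XXX001"] * 6,
            "genus": ["Triticum"] * 6,
            "accession_number": list("ABCDEF"),
            "trait": ["PH"] * 6,
            "value": [80.0, "oops", 100.0, 85.0, 95.0, 105.0],
        })
        ds = read_workbook(write_sections(tmp_path, data=data))
        assert len(ds.df) == 5
        assert len(ds.read_log) == 1
        assert ds.read_log[0]["value"] == "oops"

    def test_na_token_means_absent_not_error(self, tmp_path):
        data = pd.DataFrame({
            "study_id": ["S1"] * 3, "institute_code": ["XXX001"] * 3,
            "genus": ["Triticum"] * 3, "accession_number": list("ABC"),
            "trait": ["PH"] * 3, "value": [80.0, "NA", None],
        })
        ds = read_workbook(write_sections(tmp_path, data=data))
        assert len(ds.df) == 1
        assert ds.read_log == []

    def test_missing_sheet_named_in_error(self, tmp_path):
        path = tmp_path / "bad.xlsx"
        with pd.ExcelWriter(path) as xl:
            pd.DataFrame({"a": [1]}).to_excel(xl, sheet_name="study", index=False)
        with pytest.raises(FormatError, match="observation_variables"):
            read_workbook(path)

    def test_missing_column_named_in_error(self, tmp_path):
        data = pd.DataFrame({"study_id": ["S1"], "institute_code": ["X"],
                             "genus": ["T"], "trait": ["PH"], "value": [1.0]})
        with pytest.raises(FormatError, match="accession_number"):
            read_workbook(write_sections(tmp_path, data=data))

    def test_undefined_study_reference_rejected(self, tmp_path):
        data = pd.DataFrame({
            "study_id": ["S9"], "institute_code": ["X"], "genus": ["T"],
            "accession_number": ["A"], "trait": ["PH"], "value": [1.0]})
        with pytest.raises(FormatError, match="S9"):
            read_workbook(write_sections(tmp_path, data=data))

    def test_layout_maps_alternate_headers(self, tmp_path):
        data = pd.DataFrame({
            "study_id": ["S1"], "institute_code": ["XXX001"],
            "genus": ["Triticum"], "accession_number": ["A"],
            "observation": ["PH"], "value": [88.0]})
        path = write_sections(tmp_path, data=data)
        layout = WorkbookLayout(columns={"data": {"trait": "observation"}})
        ds = read_workbook(path, layout)
        assert ds.df["trait"].tolist() == ["PH"]

    def test_never_invents_records(self, tmp_path):
        ds = read_workbook(write_sections(tmp_path))
        assert len(ds.df) <= 6


class TestRoundTrip:
    @pytest.mark.parametrize("fmt", ["xlsx", "csv"])
    def test_simulated_dataset_survives_write_read(self, tmp_path, fmt):
        params = SimulationParams(n_accessions=40, n_years=5, seed=21)
        ds, _ = simulate_dataset(params)
        target = tmp_path / ("out.xlsx" if fmt == "xlsx" else "out")
        write_curated(ds, None, None, target)
        back = read_workbook(target)
        assert back == ds  # record multiset + trait catalogue

    def test_blues_sheet_row_counts(self, tmp_path):
        params = SimulationParams(n_accessions=10, n_years=4,
                                  replication_profile=[0, 1.0], seed=22)
        ds, _ = simulate_dataset(params)
        blues = pd.DataFrame({
            "accession_id": ds.accessions, "blue": 1.0, "se": 0.1})
        path = tmp_path / "cur.xlsx"
        write_curated(ds, blues, None, path)
        sheet = pd.read_excel(path, sheet_name="blues")
        assert len(sheet) == 10

    def test_empty_blues_still_written(self, tmp_path):
        ds, _ = simulate_dataset(SimulationParams(n_accessions=5, seed=23))
        path = tmp_path / "cur.xlsx"
        write_curated(ds, None, None, path)
        sheet = pd.read_excel(path, sheet_name="blues")
        assert len(sheet) == 0


class TestValidate:
    def test_fully_valid_dataset_has_empty_report(self, tmp_path):
        ds = read_workbook(write_sections(tmp_path))
        assert len(validate_dataset(ds)) == 0

    def test_missing_institute_reported(self):
        df = make_dataset([("A", 2001, 10.0)]).df.copy()
        df["institute_code"] = " "
        from phenocurate import PhenotypeDataset
        ds = PhenotypeDataset(df[[c for c in df.columns if c != "accession_id"]])
        rep = validate_dataset(ds)
        assert rep.codes() == ["MISSING_INSTITUTE"]

    def test_out_of_range_latitude_reported(self, tmp_path):
        study = pd.DataFrame({
            "study_id": ["S1"], "genebank": ["X"], "campaign_year": [2001],
            "location_name": ["s"], "latitude": [123.0], "longitude": [8.0],
            "seasonal_type": ["winter"], "start_date": [None], "end_date": [None],
        })
        data = pd.DataFrame({
            "study_id": ["S1"], "institute_code": ["X"], "genus": ["T"],
            "accession_number": ["A"], "trait": ["PH"], "value": [10.0]})
        ds = read_workbook(write_sections(tmp_path, study=study, data=data))
        assert "COORD_RANGE" in validate_dataset(ds).codes()

    def test_duplicate_key_reported(self):
        ds = make_dataset([("A", 2001, 10.0), ("A", 2001, 11.0)], trait="PH")
        assert "DUPLICATE_KEY" in validate_dataset(ds).codes()

    def test_unknown_trait_reported(self):
        from phenocurate import TRAIT_PRESETS
        ds = make_dataset([("A", 2001, 10.0)], trait="XYZ",
                          traits={"PH": TRAIT_PRESETS["PH"]})
        assert "UNKNOWN_TRAIT" in validate_dataset(ds).codes()

    def test_validation_is_pure(self, tmp_path):
        ds = read_workbook(write_sections(tmp_path))
        before = ds.df.copy()
        r1 = validate_dataset(ds)
        r2 = validate_dataset(ds)
        assert r1.issues == r2.issues
        pd.testing.assert_frame_equal(ds.df, before)
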