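"""Wave rate-export parsing, merging and normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xflux import (
    NormalizationTable,
    normalize_rates,
    parse_group_label,
    read_data,
    read_rate_file,
    simulate_plate,
    write_wave_workbook,
)
from xflux.errors import (
    CoverageError,
    EmptyDirectoryError,
    MalformedGroupError,
    PlateCollisionError,
    SchemaError,
    StateError,
)
from xflux.fixtures import default_fixture_spec


@pytest.mark.parametrize(
    "label, expected",
    [
        ("Group_1 MITO", ("Group_1", "MITO")),
        ("Group_2 GLYCO", ("Group_2", "GLYCO")),
        ("wt clone 3 glyco", ("wt clone 3", "GLYCO")),
        ("  padded  MITO  ", ("padded", "MITO")),
    ],
)
def test_group_label_splits_on_last_whitespace_run(label, expected):
    assert parse_group_label(label) == expected


@pytest.mark.parametrize("label", ["Group_1", "", "   ", "single"])
def test_group_label_without_assay_token_is_malformed(label):
    with pytest.raises(MalformedGroupError):
        parse_group_label(label)


def test_read_rate_file_counts_and_excludes_background(tmp_path, noiseless_table):
    # 4 groups x 3 wells x 12 measurements experimental + 4 background wells
    path = write_wave_workbook(noiseless_table, tmp_path / "p1.xlsx")
    table = read_rate_file(path)
    assert len(table) == 4 * 3 * 12
    assert table.report.background_rows == {"p1": 4 * 12}
    assert "Background" not in set(table.data["group_label"])


def test_read_rate_file_tolerates_unit_suffix_headers(tmp_path):
    df = pd.DataFrame(
        {
            "Measurement": [1, 2],
            "Well": ["A01", "A01"],
            "Group": ["G1 MITO", "G1 MITO"],
            "Time (min)": [0.0, 6.5],
            "OCR (pmol/min)": [100.0, 110.0],
            "ECAR (mpH/min)": [20.0, 21.0],
        }
    )
    df.to_csv(tmp_path / "p.csv", index=False)
    table = read_rate_file(tmp_path / "p.csv")
    assert list(table.data["ocr"]) == [100.0, 110.0]
    assert table.data["time_min"].tolist() == [0.0, 6.5]


def test_missing_ecar_column_is_schema_error(tmp_path):
    df = pd.DataFrame(
        {"Measurement": [1], "Well": ["A01"], "Group": ["G1 MITO"], "Time": [0.0], "OCR": [1.0]}
    )
    df.to_csv(tmp_path / "p.csv", index=False)
    with pytest.raises(SchemaError, match="ecar"):
        read_rate_file(tmp_path / "p.csv")


def test_blank_cells_become_flagged_nan(tmp_path):
    df = pd.DataFrame(
        {
            "Measurement": [1, 2],
            "Well": ["A01", "A01"],
            "Group": ["G1 MITO"] * 2,
            "Time": [0.0, 6.5],
            "OCR": [100.0, None],
            "ECAR": [20.0, 21.0],
        }
    )
    df.to_csv(tmp_path / "p.csv", index=False)
    table = read_rate_file(tmp_path / "p.csv")
    assert len(table) == 2  # row kept
    assert table.data["ocr"].isna().sum() == 1
    assert table.report.missing_cells == {"p": 1}


def test_read_data_merges_plates_deterministically(multi_plate_dir):
    table = read_data(multi_plate_dir)
    assert table.plates == ["plate_01", "plate_02", "plate_03"]
    sort_key = ["plate_id", "well", "assay_type", "measurement"]
    assert table.data[sort_key].equals(
        table.data[sort_key].sort_values(sort_key, kind="stable").reset_index(drop=True)
    )


def test_read_data_equals_concatenated_single_reads(plate_dir):
    merged = read_data(plate_dir)
    single = read_rate_file(sorted(plate_dir.iterdir())[0])
    pd.testing.assert_frame_equal(merged.data, single.data)


def test_duplicate_plate_stems_collide(tmp_path, noiseless_table):
    (tmp_path / "a").mkdir()
    (tmp_path / "b").mkdir()
    write_wave_workbook(noiseless_table, tmp_path / "a" / "p1.csv")
    write_wave_workbook(noiseless_table, tmp_path / "b" / "p1.csv")
    with pytest.raises(PlateCollisionError):
        read_data(tmp_path)


def test_empty_directory_errors(tmp_path):
    with pytest.raises(EmptyDirectoryError):
        read_data(tmp_path)


def _norm_table(table, quantity, unit="cells"):
    wells = table.data[["plate_id", "well"]].drop_duplicates()
    return NormalizationTable(
        pd.DataFrame(
            {
                "plate_id": wells["plate_id"],
                "well": wells["well"],
                "group": pd.NA,
                "quantity": quantity,
                "unit": unit,
            }
        )
    )


def test_normalize_by_cell_count(tmp_path, noiseless_table):
    path = write_wave_workbook(noiseless_table, tmp_path / "p1.csv")
    table = read_rate_file(path)
    norm = _norm_table(table, 30_000.0)
    out = normalize_rates(table, norm)
    # 120 pmol/min at 30k cells -> 4.0 per 1e3 cells
    basal = out.data[(out.data["assay_type"] == "MITO") & (out.data["measurement"] == 1)]
    g1 = basal[basal["exp_group"] == "Group_1"]
    assert np.allclose(g1["ocr"], 120.0 / 30.0)
    assert out.normalized and out.norm_unit == "per 1e3 cells"


def test_normalize_identity_when_quantity_equals_scale(tmp_path, noiseless_table):
    path = write_wave_workbook(noiseless_table, tmp_path / "p1.csv")
    table = read_rate_file(path)
    out = normalize_rates(table, _norm_table(table, 1000.0))
    pd.testing.assert_series_equal(out.data["ocr"], table.data["ocr"])


def test_normalize_missing_well_is_coverage_error(tmp_path, noiseless_table):
    path = write_wave_workbook(noiseless_table, tmp_path / "p1.csv")
    table = read_rate_file(path)
    norm = _norm_table(table, 1000.0)
    norm.entries.drop(norm.entries.index[0], inplace=True)
    with pytest.raises(CoverageError, match="A01"):
        normalize_rates(table, norm)


def test_double_normalization_refused(tmp_path, noiseless_table):
    path = write_wave_workbook(noiseless_table, tmp_path / "p1.csv")
    table = read_rate_file(path)
    norm = _norm_table(table, 1000.0)
    once = normalize_rates(table, norm)
    with pytest.raises(StateError):
        normalize_rates(once, norm)


@settings(max_examples=25, deadline=None)
@given(c=st.floats(min_value=0.1, max_value=50.0, allow_nan=False))
def test_normalization_is_linear_in_quantity(c, tmp_path_factory):
    """Scaling every quantity by c multiplies every rate by 1/c."""
    spec = default_fixture_spec(well_count=2)
    table = simulate_plate(spec, 0)
    path = tmp_path_factory.mktemp("lin") / "p.csv"
    write_wave_workbook(table, path)
    table = read_rate_file(path)
    base = normalize_rates(table, _norm_table(table, 1000.0))
    scaled = normalize_rates(table, _norm_table(table, 1000.0 * c))
    np.testing.assert_allclose(scaled.data["ocr"], base.data["ocr"] / c, rtol=1e-12)
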