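"""Parser-spec construction, validation against grids, and serialization."""

import json

import pytest
from hypothesis import given, settings

from plateparse.errors import SpecSchemaError
from plateparse.raw_io import CellGrid
from plateparse.spec_model import (
    AxisLabels,
    BlockRange,
    CellRef,
    ParserSpec,
    WellLayout,
    load_spec,
    save_spec,
    spec_from_dict,
    spec_to_dict,
    validate_spec,
)

from .strategies import parser_specs


def plate_spec(**overrides) -> ParserSpec:
    """A consistent horizontal single-reading 96-well spec."""
    kwargs = dict(
        data_format="horizontal",
        data_type="single",
        first_block=BlockRange(CellRef(1, 1), CellRef(1, 96)),
        num_readings=1,
        reading_names=("OD600",),
        wells=WellLayout(mode="plate", plate_rows=8, plate_cols=12),
    )
    kwargs.update(overrides)
    return ParserSpec(**kwargs)


def grid_of(n_rows: int, n_cols: int) -> CellGrid:
    return CellGrid.from_rows([["0.5"] * n_cols for _ in range(n_rows)])


class TestStructuralInvariants:
    def test_a1_style_cell_reference(self):
        assert CellRef.from_a1("C7") == CellRef(row=7, col=3)
        assert CellRef.from_a1("AA10") == CellRef(row=10, col=27)

    def test_block_must_be_rectangle(self):
        with pytest.raises(SpecSchemaError):
            BlockRange(CellRef(5, 5), CellRef(4, 9))

    def test_reading_names_must_match_count(self):
        with pytest.raises(SpecSchemaError, match="num_readings"):
            plate_spec(num_readings=2)

    def test_reading_names_must_be_unique(self):
        with pytest.raises(SpecSchemaError, match="unique"):
            plate_spec(num_readings=2, reading_names=("a", "a"))

    def test_single_forbids_axis(self):
        with pytest.raises(SpecSchemaError, match="axis"):
            plate_spec(axis=AxisLabels(mode="uniform", start=0, step=1))

    def test_timecourse_requires_axis(self):
        with pytest.raises(SpecSchemaError, match="axis"):
            plate_spec(data_type="timecourse")

    def test_matrix_requires_plate_well_layout(self):
        with pytest.raises(SpecSchemaError, match="plate"):
            plate_spec(
                data_format="matrix",
                first_block=BlockRange(CellRef(1, 1), CellRef(8, 12)),
                wells=WellLayout(mode="explicit", well_ids=("A1", "A2")),
            )

    def test_explicit_blocks_must_match_dimensions(self):
        with pytest.raises(SpecSchemaError, match="identical dimensions"):
            plate_spec(
                explicit_blocks=(BlockRange(CellRef(1, 1), CellRef(1, 95)),),
            )

    def test_default_stride_is_block_extent(self):
        spec = plate_spec(
            data_type="timecourse",
            first_block=BlockRange(CellRef(1, 1), CellRef(5, 96)),
            axis=AxisLabels(mode="uniform", start=0, step=60),
        )
        assert spec.resolved_stride == 5  # block height for horizontal
        vertical = ParserSpec(
            data_format="vertical",
            data_type="timecourse",
            first_block=BlockRange(CellRef(1, 1), CellRef(96, 5)),
            axis=AxisLabels(mode="uniform", start=0, step=60),
        )
        assert vertical.resolved_stride == 5  # block width for vertical


class TestValidateAgainstGrid:
    def test_consistent_spec_yields_empty_report(self):
        assert validate_spec(plate_spec(), grid_of(1, 96)) == []

    def test_second_block_past_grid_end_names_reading(self):
        spec = plate_spec(
            num_readings=2,
            reading_names=("OD600", "GFP"),
        )
        # stride 1: reading 2 needs row 2, grid has only 1 row
        findings = validate_spec(spec, grid_of(1, 96))
        assert [f.code for f in findings] == ["BlockOutOfBounds"]
        assert "reading 2" in findings[0].message

    def test_well_count_mismatch_off_by_one(self):
        spec = plate_spec(first_block=BlockRange(CellRef(1, 1), CellRef(1, 95)))
        findings = validate_spec(spec, grid_of(1, 95))
        assert [f.code for f in findings] == ["WellCountMismatch"]
        assert "95" in findings[0].message and "96" in findings[0].message

    def test_matrix_block_must_mimic_plate(self):
        spec = ParserSpec(
            data_format="matrix",
            data_type="single",
            first_block=BlockRange(CellRef(1, 1), CellRef(8, 11)),
        )
        codes = [f.code for f in validate_spec(spec, grid_of(8, 11))]
        assert "WellCountMismatch" in codes

    def test_axis_label_count_checked(self):
        spec = plate_spec(
            data_type="timecourse",
            first_block=BlockRange(CellRef(1, 1), CellRef(5, 96)),
            axis=AxisLabels(mode="explicit", values=(0, 60, 120)),
        )
        codes = [f.code for f in validate_spec(spec, grid_of(5, 96))]
        assert "AxisLengthMismatch" in codes

    def test_axis_ref_bounds_checked(self):
        spec = plate_spec(
            data_type="timecourse",
            first_block=BlockRange(CellRef(2, 1), CellRef(6, 96)),
            axis=AxisLabels(
                mode="from_grid",
                ref=BlockRange(CellRef(1, 97), CellRef(1, 101)),
            ),
        )
        codes = [f.code for f in validate_spec(spec, grid_of(6, 96))]
        assert "AxisRefOutOfBounds" in codes

    def test_all_findings_reported_at_once(self):
        spec = plate_spec(
            num_readings=2,
            reading_names=("a", "b"),
            first_block=BlockRange(CellRef(1, 1), CellRef(1, 95)),
        )
        codes = {f.code for f in validate_spec(spec, grid_of(1, 95))}
        assert codes == {"WellCountMismatch", "BlockOutOfBounds"}


class TestSerialization:
    def test_round_trip_json(self, tmp_path):
        spec = plate_spec(dialect="csv2", block_stride=3)
        path = tmp_path / "p.json"
        save_spec(spec, path)
        assert load_spec(path) == spec

    def test_round_trip_yaml(self, tmp_path):
        spec = plate_spec(sheet="Data 1")
        path = tmp_path / "p.yaml"
        save_spec(spec, path)
        assert load_spec(path) == spec

    def test_a1_style_accepted_in_documents(self):
        doc = spec_to_dict(plate_spec())
        doc["first_block"] = {"first": "A1", "last": "CR1"}  # col 96
        assert spec_from_dict(doc) == plate_spec()

    def test_missing_required_field_cites_it(self):
        doc = spec_to_dict(plate_spec())
        del doc["data_format"]
        with pytest.raises(SpecSchemaError, match="data_format"):
            spec_from_dict(doc)

    def test_invalid_enum_lists_allowed_values(self):
        doc = spec_to_dict(plate_spec())
        doc["data_type"] = "kinetic"
        with pytest.raises(SpecSchemaError) as err:
            spec_from_dict(doc)
        for allowed in ("single", "timecourse", "spectrum"):
            assert allowed in str(err.value)

    def test_unknown_future_fields_rejected(self):
        doc = spec_to_dict(plate_spec())
        doc["auto_detect"] = True
        with pytest.raises(SpecSchemaError, match="auto_detect"):
            spec_from_dict(doc)

    def test_wrong_schema_version_rejected(self):
        doc = spec_to_dict(plate_spec())
        doc["schema_version"] = 99
        with pytest.raises(SpecSchemaError, match="schema_version"):
            spec_from_dict(doc)

    def test_malformed_json_file(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(SpecSchemaError, match="JSON"):
            load_spec(path)

    def test_nested_error_cites_json_path(self):
        doc = spec_to_dict(plate_spec())
        doc["first_block"]["first"] = {"row": 1}
        with pytest.raises(SpecSchemaError, match="first_block.first"):
            spec_from_dict(doc)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(spec=parser_specs())
    def test_dict_round_trip_over_spec_space(self, spec):
        assert spec_from_dict(json.loads(json.dumps(spec_to_dict(spec)))) == spec
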