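"""Block location, numeric coercion and well mapping."""

import math
import random

import pytest

from plateparse.errors import BlockOutOfBounds, DimensionMismatch, NonNumericCell
from plateparse.extraction import (
    coerce_block,
    extract_all,
    locate_reading_blocks,
    map_block_to_wells,
)
from plateparse.fixtures import generate_fixture, get_style
from plateparse.raw_io import CellGrid
from plateparse.spec_model import (
    AxisLabels,
    BlockRange,
    CellRef,
    DEFAULT_SENTINELS,
    ParserSpec,
    WellLayout,
)
from plateparse.wells import enumerate_wells


def block(r1, c1, r2, c2):
    return BlockRange(CellRef(r1, c1), CellRef(r2, c2))


class TestLocateBlocks:
    def test_horizontal_default_stride_stacks_rows(self):
        spec = ParserSpec(
            data_format="horizontal",
            data_type="single",
            first_block=block(10, 2, 10, 97),
            num_readings=3,
            reading_names=("a", "b", "c"),
        )
        blocks = locate_reading_blocks(spec, None)
        assert [b.first.row for b in blocks] == [10, 11, 12]
        assert all((b.n_rows, b.n_cols) == (1, 96) for b in blocks)

    def test_single_reading_returns_first_block_unchanged(self):
        spec = ParserSpec(
            data_format="vertical",
            data_type="single",
            first_block=block(1, 1, 96, 1),
        )
        assert locate_reading_blocks(spec, None) == [spec.first_block]

    def test_matrix_stride_skips_decoration_rows(self):
        # 8 data rows + 2 decoration rows between plate grids
        spec = ParserSpec(
            data_format="matrix",
            data_type="single",
            first_block=block(5, 1, 12, 12),
            num_readings=2,
            reading_names=("OD600", "GFP"),
            block_stride=10,
        )
        second = locate_reading_blocks(spec, None)[1]
        assert (second.first.row, second.last.row) == (15, 22)

    def test_vertical_stride_moves_right(self):
        spec = ParserSpec(
            data_format="vertical",
            data_type="timecourse",
            first_block=block(1, 1, 96, 4),
            num_readings=2,
            reading_names=("a", "b"),
            axis=AxisLabels(mode="uniform", start=0, step=300),
        )
        second = locate_reading_blocks(spec, None)[1]
        assert (second.first.col, second.last.col) == (5, 8)

    def test_explicit_blocks_returned_verbatim(self):
        blocks = (block(3, 1, 3, 96), block(40, 1, 40, 96))
        spec = ParserSpec(
            data_format="horizontal",
            data_type="single",
            first_block=blocks[0],
            num_readings=2,
            reading_names=("a", "b"),
            explicit_blocks=blocks,
        )
        assert tuple(locate_reading_blocks(spec, None)) == blocks

    def test_defensive_bounds_check_with_grid(self):
        spec = ParserSpec(
            data_format="horizontal",
            data_type="single",
            first_block=block(1, 1, 1, 96),
            num_readings=2,
            reading_names=("a", "b"),
        )
        grid = CellGrid.from_rows([["0"] * 96])
        with pytest.raises(BlockOutOfBounds, match="'b'"):
            locate_reading_blocks(spec, grid)


class TestCoercion:
    def test_sentinels_and_whitespace(self):
        grid = CellGrid.from_rows([["0.42", "OVRFLW", " 1.07"]])
        out = coerce_block(grid, block(1, 1, 1, 3), DEFAULT_SENTINELS)
        assert out == [[0.42, None, 1.07]]

    def test_sentinels_case_insensitive(self):
        grid = CellGrid.from_rows([["ovrflw", "na", "Over"]])
        out = coerce_block(grid, block(1, 1, 1, 3), DEFAULT_SENTINELS)
        assert out == [[None, None, None]]

    def test_decimal_comma(self):
        grid = CellGrid.from_rows([["0,42", "1,5"]])
        out = coerce_block(grid, block(1, 1, 1, 2), DEFAULT_SENTINELS, decimal_comma=True)
        assert out == [[0.42, 1.5]]

    def test_non_numeric_cell_names_coordinates(self):
        grid = CellGrid.from_rows([["0.1", "Temp(°C)"], ["what", "0.2"]])
        with pytest.raises(NonNumericCell) as err:
            coerce_block(grid, block(1, 1, 2, 2), DEFAULT_SENTINELS)
        assert err.value.offenders == [(1, 2, "Temp(°C)"), (2, 1, "what")]

    def test_missing_is_distinct_from_zero(self):
        grid = CellGrid.from_rows([["0", ""]])
        out = coerce_block(grid, block(1, 1, 1, 2), DEFAULT_SENTINELS)
        assert out[0][0] == 0.0 and out[0][1] is None


class TestWellMapping:
    def test_matrix_cell_maps_to_plate_position(self):
        wells = enumerate_wells(8, 12)
        values = [[0.0] * 12 for _ in range(8)]
        values[1][2] = 0.9  # matrix position (2, 3)
        mapped = map_block_to_wells(values, "matrix", wells)
        assert mapped["B3"] == 0.9

    def test_horizontal_single_row_in_well_order(self):
        wells = enumerate_wells(8, 12)
        values = [[float(i) for i in range(96)]]
        mapped = map_block_to_wells(values, "horizontal", wells)
        assert mapped["A1"] == 0.0
        assert mapped["A12"] == 11.0
        assert mapped["B1"] == 12.0

    def test_transpose_duality(self):
        rng = random.Random(42)
        wells = enumerate_wells(2, 3)
        axis_len = 4
        horizontal = [[rng.random() for _ in wells] for _ in range(axis_len)]
        vertical = [list(col) for col in zip(*horizontal)]
        h = map_block_to_wells(horizontal, "horizontal", wells, axis_len)
        v = map_block_to_wells(vertical, "vertical", wells, axis_len)
        assert h == v

    def test_matrix_bijection(self):
        wells = enumerate_wells(8, 12)
        values = [[float(r * 12 + c) for c in range(12)] for r in range(8)]
        mapped = map_block_to_wells(values, "matrix", wells)
        assert sorted(mapped) == sorted(wells)
        assert sorted(mapped.values()) == [float(i) for i in range(96)]

    def test_dimension_mismatch_states_shapes(self):
        with pytest.raises(DimensionMismatch, match="1x96"):
            map_block_to_wells([[0.0] * 95], "horizontal", enumerate_wells(8, 12))


class TestExtractAll:
    def test_vertical_timecourse_fixture_dimensions(self):
        bundle = generate_fixture(get_style("vertical-timecourse-plain-excel"))
        extracted = extract_all(bundle.spec, bundle.grid())
        assert len(extracted.readings) == 2
        assert len(extracted.wells) == 96
        assert all(
            len(series) == 6
            for reading in extracted.readings
            for series in reading.values.values()
        )

    def test_minimal_single_cell(self):
        grid = CellGrid.from_rows([["7.5"]])
        spec = ParserSpec(
            data_format="horizontal",
            data_type="single",
            first_block=block(1, 1, 1, 1),
            wells=WellLayout(mode="explicit", well_ids=("A1",)),
        )
        extracted = extract_all(spec, grid)
        assert extracted.readings[0].values == {"A1": 7.5}
        assert extracted.axis_labels is None

    def test_axis_labels_read_from_grid(self):
        grid = CellGrid.from_rows(
            [
                ["t", "0", "30", "60", "90", "120"],
                ["A1", "1", "2", "3", "4", "5"],
            ]
        )
        spec = ParserSpec(
            data_format="vertical",
            data_type="timecourse",
            first_block=block(2, 2, 2, 6),
            wells=WellLayout(mode="explicit", well_ids=("A1",)),
            axis=AxisLabels(mode="from_grid", ref=block(1, 2, 1, 6)),
        )
        extracted = extract_all(spec, grid)
        assert extracted.axis_labels == (0, 30, 60, 90, 120)

    def test_textual_axis_labels_kept_as_text(self):
        grid = CellGrid.from_rows(
            [
                ["t", "0 s", "30 s"],
                ["A1", "1", "2"],
            ]
        )
        spec = ParserSpec(
            data_format="vertical",
            data_type="timecourse",
            first_block=block(2, 2, 2, 3),
            wells=WellLayout(mode="explicit", well_ids=("A1",)),
            axis=AxisLabels(mode="from_grid", ref=block(1, 2, 1, 3)),
        )
        assert extract_all(spec, grid).axis_labels == ("0 s", "30 s")

    def test_conservation_of_non_sentinel_cells(self):
        # extracted non-missing values == non-sentinel cells in the blocks
        bundle = generate_fixture(get_style("vertical-timecourse-sentinels-csv"))
        grid = bundle.grid()
        spec = bundle.spec
        blocks = locate_reading_blocks(spec, grid)
        n_non_sentinel = sum(
            not spec.is_sentinel(grid.cell(r, c))
            for b in blocks
            for r in range(b.first.row, b.last.row + 1)
            for c in range(b.first.col, b.last.col + 1)
        )
        extracted = extract_all(spec, grid)
        n_extracted = sum(
            sum(v is not None and not math.isnan(v) for v in series)
            for reading in extracted.readings
            for series in reading.values.values()
        )
        assert n_extracted == n_non_sentinel

    def test_perturbing_cells_outside_blocks_never_changes_output(self):
        bundle = generate_fixture(get_style("matrix-single-decorated-csv2"))
        spec = bundle.spec
        grid = bundle.grid()
        baseline = extract_all(spec, grid)
        protected = set()
        for b in locate_reading_blocks(spec, grid):
            protected |= {
                (r, c)
                for r in range(b.first.row, b.last.row + 1)
                for c in range(b.first.col, b.last.col + 1)
            }
        rng = random.Random(7)
        rows = [list(r) for r in grid.cells]
        for i in range(100):
            r = rng.randrange(1, grid.n_rows + 1)
            c = rng.randrange(1, grid.n_cols + 1)
            if (r, c) in protected:
                continue
            perturbed = [list(row) for row in rows]
            perturbed[r - 1][c - 1] = f"JUNK{i}"
            result = extract_all(
                spec, CellGrid.from_rows(perturbed, source_dialect=grid.source_dialect)
            )
            assert result == baseline
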