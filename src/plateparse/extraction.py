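"""Applying a parser spec to a raw grid: locate, coerce, map.

Extraction is purely positional: only the cells inside the located reading
blocks (and the axis reference range, if labels are read from the grid)
ever influence the output. Everything else in the file — preamble lines,
instrument chatter, footers — is ignored by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import AxisLengthMismatch, BlockOutOfBounds, DimensionMismatch, NonNumericCell
from .raw_io import CellGrid
from .spec_model import BlockRange, ParserSpec
from .wells import well_position

logger = logging.getLogger(__name__)

#: Marker for a missing measurement (sentinel cell); distinct from 0.0.
MISSING = None


@dataclass(frozen=True)
class ReadingData:
    """One measurement channel over all wells.

    ``values`` maps canonical well id to a scalar (single) or an ordered
    list over the time/wavelength axis. Missing entries are ``None``.
    """

    name: str
    values: dict


@dataclass(frozen=True)
class ExtractedData:
    """All readings pulled from one raw file, plus shared axis labels."""

    readings: tuple[ReadingData, ...]
    axis_labels: tuple | None = None

    @property
    def wells(self) -> list[str]:
        return list(self.readings[0].values) if self.readings else []


def locate_reading_blocks(spec: ParserSpec, grid: CellGrid | None) -> list[BlockRange]:
    """Rectangles of all ``num_readings`` reading blocks, in reading order.

    With ``explicit_blocks`` they are returned verbatim. Otherwise block i
    starts ``stride * (i-1)`` rows below the first block (horizontal and
    matrix layouts stack readings downward) or columns to its right
    (vertical layouts place readings side by side). Pass a grid to get a
    defensive bounds re-check; ``validate_spec`` reports the same problem
    as a finding.
    """
    if spec.explicit_blocks is not None:
        blocks = list(spec.explicit_blocks)
    else:
        stride = spec.resolved_stride
        vertical = spec.data_format == "vertical"
        blocks = [
            spec.first_block.shifted(
                d_rows=0 if vertical else stride * i,
                d_cols=stride * i if vertical else 0,
            )
            for i in range(spec.num_readings)
        ]
    if grid is not None:
        for name, blk in zip(spec.reading_names, blocks):
            if blk.last.row > grid.n_rows or blk.last.col > grid.n_cols:
                raise BlockOutOfBounds(
                    f"block for reading {name!r} (rows {blk.first.row}-{blk.last.row}, "
                    f"cols {blk.first.col}-{blk.last.col}) exceeds the "
                    f"{grid.n_rows}x{grid.n_cols} grid"
                )
            logger.debug(
                "reading %r block: rows %d-%d, cols %d-%d",
                name, blk.first.row, blk.last.row, blk.first.col, blk.last.col,
            )
    return blocks


def _parse_number(text: str, decimal_comma: bool) -> float:
    s = text.strip()
    if decimal_comma:
        s = s.replace(".", "").replace(",", ".") if "," in s else s
    return float(s)


def coerce_block(
    grid: CellGrid,
    block: BlockRange,
    sentinels: tuple[str, ...],
    decimal_comma: bool = False,
) -> list[list[float | None]]:
    """Turn a rectangle of cell text into numbers and missing markers.

    Cells are stripped; sentinel tokens (case-insensitive) become ``None``;
    with ``decimal_comma`` (csv2 exports) the decimal comma is converted
    before parsing. Any remaining unparseable cell is collected and
    reported — all offenders at once — as :class:`NonNumericCell` with grid
    coordinates, so the user can fix the block selection in the spec.
    """
    sentinel_set = {s.strip().lower() for s in sentinels}
    out: list[list[float | None]] = []
    offenders: list[tuple[int, int, str]] = []
    for r in range(block.first.row, block.last.row + 1):
        row_vals: list[float | None] = []
        for c in range(block.first.col, block.last.col + 1):
            text = grid.cell(r, c)
            if text.strip().lower() in sentinel_set:
                row_vals.append(MISSING)
                continue
            try:
                row_vals.append(_parse_number(text, decimal_comma))
            except ValueError:
                offenders.append((r, c, text))
                row_vals.append(MISSING)
        out.append(row_vals)
    if offenders:
        raise NonNumericCell(offenders)
    return out


def map_block_to_wells(
    values: list[list[float | None]],
    data_format: str,
    wells: list[str],
    axis_len: int = 1,
) -> dict:
    """Assign coerced block values to wells according to the layout.

    horizontal: column j belongs to wells[j], row t to axis position t;
    vertical: row i belongs to wells[i], column t to axis position t;
    matrix: cell (r, c) belongs to the well at plate position (r, c) —
    the block visually mimics the plate.
    Returns well -> scalar when ``axis_len == 1`` else well -> list.
    """
    n_rows = len(values)
    n_cols = len(values[0]) if values else 0

    if data_format == "horizontal":
        if n_rows != axis_len or n_cols != len(wells):
            raise DimensionMismatch(
                f"horizontal block must be axis_len x n_wells = {axis_len}x{len(wells)}, "
                f"got {n_rows}x{n_cols}"
            )
        series = {w: [values[t][j] for t in range(axis_len)] for j, w in enumerate(wells)}
    elif data_format == "vertical":
        if n_rows != len(wells) or n_cols != axis_len:
            raise DimensionMismatch(
                f"vertical block must be n_wells x axis_len = {len(wells)}x{axis_len}, "
                f"got {n_rows}x{n_cols}"
            )
        series = {w: list(values[i]) for i, w in enumerate(wells)}
    elif data_format == "matrix":
        if axis_len != 1:
            raise DimensionMismatch("matrix blocks hold a single value per well")
        if n_rows * n_cols != len(wells):
            raise DimensionMismatch(
                f"matrix block is {n_rows}x{n_cols} = {n_rows * n_cols} cells "
                f"but the layout lists {len(wells)} wells"
            )
        series = {}
        for w in wells:
            pr, pc = well_position(w)
            if pr > n_rows or pc > n_cols:
                raise DimensionMismatch(
                    f"well {w} maps to plate position ({pr},{pc}) outside the "
                    f"{n_rows}x{n_cols} matrix block"
                )
            series[w] = [values[pr - 1][pc - 1]]
    else:  # pragma: no cover - formats validated upstream
        raise DimensionMismatch(f"unknown data format {data_format!r}")

    if axis_len == 1:
        return {w: v[0] for w, v in series.items()}
    return series


def _resolve_axis_labels(spec: ParserSpec, grid: CellGrid, decimal_comma: bool):
    ax = spec.axis
    if ax is None:
        return None
    n = spec.axis_length
    if ax.mode == "explicit":
        labels = list(ax.values)
    elif ax.mode == "uniform":
        start, step = ax.start, ax.step
        labels = [start + i * step for i in range(n)]
        if float(start).is_integer() and float(step).is_integer():
            labels = [int(v) for v in labels]
    else:  # from_grid
        ref = ax.ref
        if ref.last.row > grid.n_rows or ref.last.col > grid.n_cols:
            raise AxisLengthMismatch(
                f"axis.ref exceeds the {grid.n_rows}x{grid.n_cols} grid"
            )
        cells = [
            grid.cell(r, c).strip()
            for r in range(ref.first.row, ref.last.row + 1)
            for c in range(ref.first.col, ref.last.col + 1)
        ]
        try:
            labels = [_parse_number(t, decimal_comma) for t in cells]
            labels = [int(v) if v.is_integer() else v for v in labels]
        except ValueError:
            labels = cells  # time rows sometimes read "0 s", "30 s" — keep text
    if len(labels) != n:
        raise AxisLengthMismatch(
            f"resolved {len(labels)} axis labels but the block implies {n} "
            f"{spec.axis_name} points"
        )
    return tuple(labels)


def extract_all(spec: ParserSpec, grid: CellGrid) -> ExtractedData:
    """Locate every reading block, coerce it, and map values to wells.

    The grid's source dialect decides decimal-comma handling (csv2); the
    spec's dialect hint is the fallback when a grid was built in memory.
    """
    decimal_comma = (grid.source_dialect == "csv2") or (spec.dialect == "csv2")
    blocks = locate_reading_blocks(spec, grid)
    wells = spec.wells.wells()
    axis_len = spec.axis_length
    readings = []
    for name, blk in zip(spec.reading_names, blocks):
        matrix = coerce_block(grid, blk, spec.sentinel_values, decimal_comma)
        values = map_block_to_wells(matrix, spec.data_format, wells, axis_len)
        readings.append(ReadingData(name=name, values=values))
    axis_labels = _resolve_axis_labels(spec, grid, decimal_comma)
    return ExtractedData(readings=tuple(readings), axis_labels=axis_labels)
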