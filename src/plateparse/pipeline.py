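"""End-to-end composition: raw grid + spec + metadata -> joined table.

Thin glue over the stage modules, shared by the CLI and by programmatic
callers (including the test fixtures' round-trip checks).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import ValidationFailed
from .extraction import extract_all
from .raw_io import CellGrid, MetadataTable, read_metadata, read_raw_grid
from .spec_model import ParserSpec, load_spec, validate_spec
from .tidy_join import build_tidy, join_metadata


def parse_grid(
    spec: ParserSpec,
    grid: CellGrid,
    metadata: MetadataTable | None = None,
    axis_name: str | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Validate, extract, tidy and (optionally) join, all in memory.

    Raises :class:`ValidationFailed` carrying the findings when the spec
    does not fit the grid. Returns the table and any join warnings.
    """
    findings = validate_spec(spec, grid)
    if findings:
        raise ValidationFailed(findings)
    extracted = extract_all(spec, grid)
    tidy = build_tidy(extracted, spec, axis_name=axis_name)
    if metadata is None:
        return tidy, []
    return join_metadata(tidy, metadata)


def parse_files(
    parser_path: str | Path,
    data_path: str | Path,
    metadata_path: str | Path | None = None,
    dialect: str | None = None,
    sheet: str | int | None = None,
    delimiter: str | None = None,
    axis_name: str | None = None,
) -> tuple[pd.DataFrame, list[str], ParserSpec, CellGrid]:
    """File-level pipeline: load spec, read raw + metadata, parse.

    Explicit dialect/sheet/delimiter arguments override the spec's hints.
    """
    spec = load_spec(parser_path)
    grid = read_raw_grid(
        data_path,
        dialect=dialect if dialect is not None else spec.dialect,
        sheet=sheet if sheet is not None else spec.sheet,
        delimiter=delimiter if delimiter is not None else spec.delimiter,
    )
    metadata = read_metadata(metadata_path) if metadata_path is not None else None
    table, warnings = parse_grid(spec, grid, metadata, axis_name=axis_name)
    return table, warnings, spec, grid
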