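"""Reshaping extracted data into tidy tables and joining metadata.

A tidy table has one row per well (single readings) or per (well,
time/wavelength) pair, one column per reading, every column a variable and
every cell a single value. Joining attaches the user's metadata on the
well key, metadata on the left and measurements on the right — the shape
downstream growth-curve and fluorescence analysis tools consume.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import PathUnwritable
from .extraction import ExtractedData
from .raw_io import MetadataTable
from .spec_model import ParserSpec


def build_tidy(
    extracted: ExtractedData,
    spec: ParserSpec,
    axis_name: str | None = None,
) -> pd.DataFrame:
    """Long over wells (and axis), wide over readings.

    Columns: ``well`` [+ ``time`` or ``wavelength``] then one column per
    reading in spec order. Rows follow spec well order, with axis labels in
    order within each well. Missing measurements are ``NaN`` (never zero).
    """
    if axis_name is None:
        axis_name = spec.axis_name or None
    wells = extracted.wells
    names = [r.name for r in extracted.readings]

    if extracted.axis_labels is None:
        data = {"well": wells}
        for reading in extracted.readings:
            data[reading.name] = [reading.values[w] for w in wells]
        return pd.DataFrame(data, columns=["well"] + names)

    labels = list(extracted.axis_labels)
    rows = {
        "well": [w for w in wells for _ in labels],
        axis_name: [lab for _ in wells for lab in labels],
    }
    for reading in extracted.readings:
        rows[reading.name] = [v for w in wells for v in reading.values[w]]
    return pd.DataFrame(rows, columns=["well", axis_name] + names)


def join_metadata(
    tidy: pd.DataFrame,
    metadata: MetadataTable,
) -> tuple[pd.DataFrame, list[str]]:
    """Attach metadata to every tidy row by canonical well match.

    All data rows are retained: wells absent from the metadata keep their
    measurements and get empty metadata fields, with a warning naming them.
    Metadata rows for wells absent from the data are dropped, also with a
    warning. Output columns are the metadata columns (well moved first)
    followed by the tidy table's axis and reading columns.
    """
    warnings: list[str] = []
    meta = metadata.table.copy()
    well_col = metadata.well_column
    if well_col != "well":
        meta = meta.rename(columns={well_col: "well"})
    meta = meta[["well"] + [c for c in meta.columns if c != "well"]]

    data_wells = set(tidy["well"])
    meta_wells = set(meta["well"])
    missing_meta = sorted(data_wells - meta_wells)
    unused_meta = sorted(meta_wells - data_wells)
    if missing_meta:
        warnings.append(
            "no metadata for data well(s): " + ", ".join(missing_meta)
        )
    if unused_meta:
        warnings.append(
            "metadata well(s) absent from the data were dropped: "
            + ", ".join(unused_meta)
        )

    joined = tidy.merge(meta, on="well", how="left")
    meta_cols = list(meta.columns)
    data_cols = [c for c in tidy.columns if c != "well"]
    return joined[meta_cols + data_cols], warnings


def write_output(joined: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write the joined table as UTF-8 delimited text.

    One header row; missing values become empty fields; numbers keep full
    precision (a re-read reproduces the values exactly).
    """
    try:
        joined.to_csv(path, sep=sep, index=False, na_rep="", encoding="utf-8")
    except OSError as exc:
        raise PathUnwritable(f"cannot write {path}: {exc}") from exc
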