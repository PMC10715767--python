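"""Reading raw plate-reader export files and metadata tables.

Raw exports are read into a :class:`CellGrid` — a rectangular grid of text
cells with 1-based addressing that reproduces the file exactly as a user
would see it in a spreadsheet program. No header inference, no row skipping,
no type coercion happens at this stage: parser-spec coordinates refer to
this grid, so what you see is what you address.

Five dialects are accepted: ``csv`` (comma separator, period decimal),
``csv2`` (semicolon separator, comma decimal — the European spreadsheet
convention), ``tsv``, ``txt`` (tab-separated by default, overridable
delimiter) and ``excel`` (.xlsx workbooks). ``csv2`` shares the ``.csv``
extension with ``csv`` and is therefore never inferred — it must be
requested explicitly.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import (
    DuplicateWell,
    FileUnreadable,
    MissingWellColumn,
    SheetNotFound,
    UnknownDialect,
)
from .wells import canonicalize_well

logger = logging.getLogger(__name__)

DIALECTS = ("csv", "csv2", "tsv", "txt", "excel")

_DELIMITERS = {"csv": ",", "csv2": ";", "tsv": "\t", "txt": "\t"}

_EXTENSION_DIALECTS = {
    ".csv": "csv",
    ".tsv": "tsv",
    ".txt": "txt",
    ".xlsx": "excel",
    ".xls": "excel",
}


@dataclass(frozen=True)
class CellGrid:
    """A rectangular grid of raw text cells representing one export file.

    Addressing is 1-based: ``cell(1, 1)`` is the top-left cell of the file.
    Short rows are right-padded with empty strings at read time so every row
    has exactly ``n_cols`` entries. All values are text; numeric coercion
    happens later, during extraction.
    """

    cells: tuple[tuple[str, ...], ...]
    source_dialect: str = "csv"
    source_sheet: str | None = None

    @property
    def n_rows(self) -> int:
        return len(self.cells)

    @property
    def n_cols(self) -> int:
        return len(self.cells[0]) if self.cells else 0

    def cell(self, row: int, col: int) -> str:
        """Text content of the cell at 1-based (row, col)."""
        if not (1 <= row <= self.n_rows and 1 <= col <= self.n_cols):
            raise IndexError(
                f"cell ({row},{col}) outside grid of {self.n_rows}x{self.n_cols}"
            )
        return self.cells[row - 1][col - 1]

    @classmethod
    def from_rows(
        cls,
        rows: Sequence[Sequence[str]],
        source_dialect: str = "csv",
        source_sheet: str | None = None,
    ) -> "CellGrid":
        """Build a grid from row lists, right-padding short rows."""
        width = max((len(r) for r in rows), default=0)
        padded = tuple(
            tuple(list(map(str, r)) + [""] * (width - len(r))) for r in rows
        )
        return cls(padded, source_dialect, source_sheet)


@dataclass
class MetadataTable:
    """User experiment annotations keyed on a well column.

    ``table`` preserves the file's column order; ``well_column`` is the
    resolved name of the well-key column (case-insensitive match on the
    stripped header). Well values are canonicalized and must be unique.
    """

    table: pd.DataFrame
    well_column: str = "well"

    @property
    def columns(self) -> list[str]:
        return list(self.table.columns)

    @property
    def wells(self) -> list[str]:
        return list(self.table[self.well_column])

    def __len__(self) -> int:
        return len(self.table)


def infer_dialect(path: str | Path) -> str:
    """Dialect from file extension. csv2 is never inferred (shared .csv)."""
    ext = Path(path).suffix.lower()
    try:
        return _EXTENSION_DIALECTS[ext]
    except KeyError:
        raise UnknownDialect(
            f"cannot infer dialect from extension {ext!r} of {path}; "
            f"pass one of {DIALECTS} explicitly"
        ) from None


def _read_text(path: Path) -> str:
    """UTF-8 first, latin-1 fallback with a logged warning."""
    data = path.read_bytes()
    try:
        return data.decode("utf-8-sig")
    except UnicodeDecodeError:
        logger.warning("%s is not valid UTF-8; falling back to latin-1", path)
        return data.decode("latin-1")


def _stringify_excel(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "TRUE" if value else "FALSE"
    if isinstance(value, float):
        return str(int(value)) if value.is_integer() else str(value)
    return str(value)


def _read_excel_rows(path: Path, sheet: str | int | None) -> tuple[list[list[str]], str]:
    try:
        import openpyxl

        wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
    except FileNotFoundError:
        raise FileUnreadable(f"file not found: {path}") from None
    except Exception as exc:  # zip/BIFF errors from openpyxl
        if path.suffix.lower() == ".xls":
            raise FileUnreadable(
                f"{path}: legacy .xls workbooks are not supported; "
                "convert to .xlsx or export as CSV/TSV"
            ) from exc
        raise FileUnreadable(f"cannot open workbook {path}: {exc}") from exc
    try:
        if sheet is None:
            ws = wb.worksheets[0]
        elif isinstance(sheet, int) or (isinstance(sheet, str) and sheet.isdigit()):
            idx = int(sheet)
            if not 1 <= idx <= len(wb.worksheets):
                raise SheetNotFound(
                    f"sheet index {idx} out of range; workbook has "
                    f"{len(wb.worksheets)} sheet(s)"
                )
            ws = wb.worksheets[idx - 1]
        else:
            if sheet not in wb.sheetnames:
                raise SheetNotFound(
                    f"sheet {sheet!r} not found; available: {wb.sheetnames}"
                )
            ws = wb[sheet]
        rows = [[_stringify_excel(v) for v in row] for row in ws.iter_rows(values_only=True)]
        return rows, ws.title
    finally:
        wb.close()


def read_raw_grid(
    path: str | Path,
    dialect: str | None = None,
    sheet: str | int | None = None,
    delimiter: str | None = None,
) -> CellGrid:
    """Read a raw export file into a :class:`CellGrid`, verbatim.

    Parameters
    ----------
    path
        The export file. Extension decides the dialect unless ``dialect``
        is given (required for csv2, which shares ``.csv``).
    dialect
        One of ``csv, csv2, tsv, txt, excel``.
    sheet
        Excel only: sheet name or 1-based index; defaults to the first sheet.
    delimiter
        Overrides the separator for text dialects (e.g. space-delimited
        ``.txt`` exports).
    """
    path = Path(path)
    if dialect is None:
        dialect = infer_dialect(path)
    if dialect not in DIALECTS:
        raise UnknownDialect(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")

    if dialect == "excel":
        rows, title = _read_excel_rows(path, sheet)
        return CellGrid.from_rows(rows, source_dialect="excel", source_sheet=title)

    try:
        text = _read_text(path)
    except FileNotFoundError:
        raise FileUnreadable(f"file not found: {path}") from None
    except OSError as exc:
        raise FileUnreadable(f"cannot read {path}: {exc}") from exc

    sep = delimiter if delimiter is not None else _DELIMITERS[dialect]
    reader = csv.reader(io.StringIO(text), delimiter=sep, quotechar='"')
    rows = [list(r) for r in reader]
    return CellGrid.from_rows(rows, source_dialect=dialect)


def write_grid(grid_rows: Sequence[Sequence[str]], path: str | Path,
               dialect: str = "csv", sheet_name: str = "Sheet1") -> None:
    """Serialize rows of text cells in the given dialect (fixture support)."""
    path = Path(path)
    if dialect == "excel":
        import openpyxl

        wb = openpyxl.Workbook()
        ws = wb.active
        ws.title = sheet_name
        for r, row in enumerate(grid_rows, start=1):
            for c, value in enumerate(row, start=1):
                if value != "":
                    ws.cell(row=r, column=c, value=str(value))
        wb.save(path)
        return
    if dialect not in _DELIMITERS:
        raise UnknownDialect(f"unknown dialect {dialect!r}")
    sep = _DELIMITERS[dialect]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=sep, quotechar='"')
        for row in grid_rows:
            writer.writerow(row)


def resolve_well_column(columns: Sequence[str]) -> str:
    """First column whose stripped name case-insensitively equals 'well'."""
    for col in columns:
        if str(col).strip().lower() == "well":
            return col
    raise MissingWellColumn(
        "metadata must contain a 'well' column; found columns: "
        + ", ".join(repr(c) for c in columns)
    )


def metadata_from_grid(grid: CellGrid) -> MetadataTable:
    """Interpret a text grid as a metadata table (first row = header).

    The well column is resolved case-insensitively, its values are
    canonicalized (``a01`` -> ``A1``) and must be unique. Other columns are
    coerced to numeric where every non-empty entry parses, else kept as text.
    """
    if grid.n_rows == 0:
        raise MissingWellColumn("metadata table is empty")
    header = [h.strip() for h in grid.cells[0]]
    well_col = resolve_well_column(header)
    df = pd.DataFrame(list(grid.cells[1:]), columns=header)

    df[well_col] = [canonicalize_well(w) for w in df[well_col]]
    dup = df[well_col][df[well_col].duplicated()].unique().tolist()
    if dup:
        raise DuplicateWell(
            f"duplicate well(s) in metadata after canonicalization: {', '.join(dup)}"
        )
    for col in df.columns:
        if col == well_col:
            continue
        nonempty = df[col][df[col] != ""]
        if len(nonempty):
            converted = pd.to_numeric(nonempty, errors="coerce")
            if not converted.isna().any():
                df[col] = pd.to_numeric(df[col].replace("", pd.NA))
        df[col] = df[col].replace("", pd.NA) if df[col].dtype == object else df[col]
    return MetadataTable(table=df, well_column=well_col)


def read_metadata(
    path: str | Path,
    dialect: str | None = None,
    sheet: str | int | None = None,
    delimiter: str | None = None,
) -> MetadataTable:
    """Read a metadata file (any accepted dialect, first row = header)."""
    grid = read_raw_grid(path, dialect=dialect, sheet=sheet, delimiter=delimiter)
    return metadata_from_grid(grid)
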