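"""The declarative parser specification and its JSON/YAML serialization.

A :class:`ParserSpec` is the persistent description of where and how
measurement data lives inside a raw export grid: the layout convention
(horizontal, vertical or matrix), the data type (single reading per well,
timecourse or spectrum), the rectangle of the first reading block, how
subsequent reading blocks are placed (a stride, or explicit rectangles),
the well layout, and the time/wavelength axis labels. Saving and re-loading
a spec lets the same export format be parsed again without re-specifying
anything — the spec file *is* the reusable parser.

Coordinates are 1-based (row, col) to match what a user sees in a
spreadsheet program; spreadsheet-style references like ``"C7"`` are
accepted in spec files and converted on load.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

from .errors import SpecSchemaError
from .wells import canonicalize_well, enumerate_wells

SCHEMA_VERSION = 1

DATA_FORMATS = ("horizontal", "vertical", "matrix")
DATA_TYPES = ("single", "timecourse", "spectrum")
AXIS_MODES = ("explicit", "from_grid", "uniform")
WELL_MODES = ("plate", "explicit")

#: Tokens treated as missing values inside data blocks (case-insensitive).
#: Instruments write overflow/underflow markers instead of numbers; the
#: empty string covers truncated rows.
DEFAULT_SENTINELS = ("", "NA", "OVRFLW", "OVER", "Overflow", "?")

_A1_RE = re.compile(r"^([A-Za-z]+)([1-9][0-9]*)$")


def _col_letters_to_index(letters: str) -> int:
    idx = 0
    for ch in letters.upper():
        idx = idx * 26 + (ord(ch) - ord("A") + 1)
    return idx


@dataclass(frozen=True)
class CellRef:
    """A single grid cell, 1-based (row, col)."""

    row: int
    col: int

    def __post_init__(self):
        if self.row < 1 or self.col < 1:
            raise SpecSchemaError(
                f"cell reference must be 1-based, got row={self.row}, col={self.col}"
            )

    @classmethod
    def from_a1(cls, ref: str) -> "CellRef":
        """Parse a spreadsheet-style reference: ``"C7"`` -> row 7, col 3."""
        m = _A1_RE.match(ref.strip())
        if m is None:
            raise SpecSchemaError(f"cannot parse cell reference {ref!r}")
        return cls(row=int(m.group(2)), col=_col_letters_to_index(m.group(1)))


@dataclass(frozen=True)
class BlockRange:
    """A rectangle of grid cells, from ``first`` to ``last`` inclusive."""

    first: CellRef
    last: CellRef

    def __post_init__(self):
        if self.first.row > self.last.row or self.first.col > self.last.col:
            raise SpecSchemaError(
                "block range is not a rectangle: first cell "
                f"({self.first.row},{self.first.col}) must not lie below or right "
                f"of last cell ({self.last.row},{self.last.col})"
            )

    @property
    def n_rows(self) -> int:
        return self.last.row - self.first.row + 1

    @property
    def n_cols(self) -> int:
        return self.last.col - self.first.col + 1

    def shifted(self, d_rows: int = 0, d_cols: int = 0) -> "BlockRange":
        return BlockRange(
            CellRef(self.first.row + d_rows, self.first.col + d_cols),
            CellRef(self.last.row + d_rows, self.last.col + d_cols),
        )

    def contains(self, row: int, col: int) -> bool:
        return (
            self.first.row <= row <= self.last.row
            and self.first.col <= col <= self.last.col
        )


@dataclass(frozen=True)
class AxisLabels:
    """Where the time/wavelength labels come from.

    ``explicit``: ``values`` lists the labels in order.
    ``from_grid``: ``ref`` is a single-row or single-column rectangle in the
    raw grid whose cell texts are the labels (coerced to numbers when all
    of them parse).
    ``uniform``: an arithmetic sequence ``start, start+step, ...`` with as
    many terms as the block's axis dimension.
    """

    mode: str
    values: tuple | None = None
    ref: BlockRange | None = None
    start: float | None = None
    step: float | None = None

    def __post_init__(self):
        if self.mode not in AXIS_MODES:
            raise SpecSchemaError(
                f"axis.mode must be one of {AXIS_MODES}, got {self.mode!r}"
            )
        if self.mode == "explicit":
            if not self.values:
                raise SpecSchemaError("axis.values is required when axis.mode=explicit")
            if self.ref is not None or self.start is not None or self.step is not None:
                raise SpecSchemaError("axis.mode=explicit takes only axis.values")
        elif self.mode == "from_grid":
            if self.ref is None:
                raise SpecSchemaError("axis.ref is required when axis.mode=from_grid")
            if self.ref.n_rows != 1 and self.ref.n_cols != 1:
                raise SpecSchemaError(
                    "axis.ref must be a single row or a single column, got "
                    f"{self.ref.n_rows}x{self.ref.n_cols}"
                )
            if self.values is not None or self.start is not None or self.step is not None:
                raise SpecSchemaError("axis.mode=from_grid takes only axis.ref")
        else:  # uniform
            if self.start is None or self.step is None:
                raise SpecSchemaError(
                    "axis.start and axis.step are required when axis.mode=uniform"
                )
            if self.values is not None or self.ref is not None:
                raise SpecSchemaError("axis.mode=uniform takes only axis.start/axis.step")


@dataclass(frozen=True)
class WellLayout:
    """Which wells the data block covers, in order.

    ``plate`` mode generates row-major identifiers for a ``plate_rows`` x
    ``plate_cols`` plate (A1, A2, ...); ``explicit`` mode lists well ids in
    the order they appear along the block's well axis.
    """

    mode: str
    plate_rows: int | None = None
    plate_cols: int | None = None
    well_ids: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.mode not in WELL_MODES:
            raise SpecSchemaError(
                f"wells.mode must be one of {WELL_MODES}, got {self.mode!r}"
            )
        if self.mode == "plate":
            if not self.plate_rows or not self.plate_cols:
                raise SpecSchemaError(
                    "wells.plate_rows and wells.plate_cols are required in plate mode"
                )
            if self.well_ids is not None:
                raise SpecSchemaError("wells.well_ids is not allowed in plate mode")
        else:
            if not self.well_ids:
                raise SpecSchemaError(
                    "wells.well_ids must be a non-empty list in explicit mode"
                )
            if self.plate_rows is not None or self.plate_cols is not None:
                raise SpecSchemaError(
                    "wells.plate_rows/plate_cols are not allowed in explicit mode"
                )
            canon = [canonicalize_well(w) for w in self.well_ids]
            dup = {w for w in canon if canon.count(w) > 1}
            if dup:
                raise SpecSchemaError(
                    f"wells.well_ids contains duplicates after canonicalization: {sorted(dup)}"
                )

    def wells(self) -> list[str]:
        if self.mode == "plate":
            return enumerate_wells(self.plate_rows, self.plate_cols)
        return [canonicalize_well(w) for w in self.well_ids]


@dataclass(frozen=True)
class ParserSpec:
    """The complete declarative description of one export format.

    ``block_stride`` is the number of grid rows (horizontal/matrix) or
    columns (vertical) between the *starts* of consecutive reading blocks;
    it defaults to the block height/width, i.e. immediately adjacent blocks.
    ``explicit_blocks`` overrides stride placement for irregular exports.
    ``sentinel_values`` are the case-insensitive tokens treated as missing.
    Dialect hints record how the raw file should be read.
    """

    data_format: str
    data_type: str
    first_block: BlockRange
    num_readings: int = 1
    reading_names: tuple[str, ...] = ("value",)
    block_stride: int | None = None
    explicit_blocks: tuple[BlockRange, ...] | None = None
    wells: WellLayout = field(
        default_factory=lambda: WellLayout(mode="plate", plate_rows=8, plate_cols=12)
    )
    axis: AxisLabels | None = None
    sentinel_values: tuple[str, ...] = DEFAULT_SENTINELS
    dialect: str | None = None
    sheet: str | int | None = None
    delimiter: str | None = None

    def __post_init__(self):
        if self.data_format not in DATA_FORMATS:
            raise SpecSchemaError(
                f"data_format must be one of {DATA_FORMATS}, got {self.data_format!r}"
            )
        if self.data_type not in DATA_TYPES:
            raise SpecSchemaError(
                f"data_type must be one of {DATA_TYPES}, got {self.data_type!r}"
            )
        if self.num_readings < 1:
            raise SpecSchemaError(f"num_readings must be >= 1, got {self.num_readings}")
        if len(self.reading_names) != self.num_readings:
            raise SpecSchemaError(
                f"reading_names has {len(self.reading_names)} entries but "
                f"num_readings is {self.num_readings}"
            )
        if len(set(self.reading_names)) != len(self.reading_names):
            raise SpecSchemaError("reading_names must be unique")
        if any(not str(n).strip() for n in self.reading_names):
            raise SpecSchemaError("reading_names must be non-empty")
        if self.block_stride is not None and self.block_stride < 1:
            raise SpecSchemaError(f"block_stride must be >= 1, got {self.block_stride}")
        if self.explicit_blocks is not None:
            if len(self.explicit_blocks) != self.num_readings:
                raise SpecSchemaError(
                    f"explicit_blocks has {len(self.explicit_blocks)} entries but "
                    f"num_readings is {self.num_readings}"
                )
            for i, blk in enumerate(self.explicit_blocks, start=1):
                if (blk.n_rows, blk.n_cols) != (
                    self.first_block.n_rows,
                    self.first_block.n_cols,
                ):
                    raise SpecSchemaError(
                        f"explicit_blocks[{i - 1}] is {blk.n_rows}x{blk.n_cols} but "
                        f"first_block is {self.first_block.n_rows}x{self.first_block.n_cols}; "
                        "all reading blocks must have identical dimensions"
                    )
        if self.data_type == "single" and self.axis is not None:
            raise SpecSchemaError("axis must be absent when data_type=single")
        if self.data_type != "single" and self.axis is None:
            raise SpecSchemaError(f"axis is required when data_type={self.data_type}")
        if self.data_format == "matrix":
            if self.data_type != "single":
                raise SpecSchemaError(
                    "matrix format holds one value per well per block; use one "
                    "reading per timepoint (stride or explicit_blocks) instead of "
                    f"data_type={self.data_type!r}"
                )
            if self.wells.mode != "plate":
                raise SpecSchemaError(
                    "matrix format requires wells.mode=plate (the block mimics the plate)"
                )
        if self.dialect is not None and self.dialect not in (
            "csv",
            "csv2",
            "tsv",
            "txt",
            "excel",
        ):
            raise SpecSchemaError(f"unknown dialect hint {self.dialect!r}")

    # -- derived geometry -------------------------------------------------

    @property
    def axis_length(self) -> int:
        """Number of time/wavelength points implied by the block shape."""
        if self.data_type == "single" or self.data_format == "matrix":
            return 1
        if self.data_format == "horizontal":
            return self.first_block.n_rows
        return self.first_block.n_cols

    @property
    def well_axis_length(self) -> int:
        """Block extent along the well axis."""
        if self.data_format == "horizontal":
            return self.first_block.n_cols
        if self.data_format == "vertical":
            return self.first_block.n_rows
        return self.first_block.n_rows * self.first_block.n_cols

    @property
    def resolved_stride(self) -> int:
        if self.block_stride is not None:
            return self.block_stride
        if self.data_format == "vertical":
            return self.first_block.n_cols
        return self.first_block.n_rows

    @property
    def axis_name(self) -> str:
        return {"timecourse": "time", "spectrum": "wavelength"}.get(self.data_type, "")

    def is_sentinel(self, text: str) -> bool:
        stripped = text.strip().lower()
        return any(stripped == s.strip().lower() for s in self.sentinel_values)


# -- grid-dependent validation -------------------------------------------


@dataclass(frozen=True)
class Finding:
    """One validation problem: a machine-readable code plus a human message."""

    code: str
    message: str

    def __str__(self) -> str:
        return f"{self.code}: {self.message}"


def _block_findings(blocks, grid, findings):
    for i, blk in enumerate(blocks, start=1):
        if blk.last.row > grid.n_rows or blk.last.col > grid.n_cols:
            findings.append(
                Finding(
                    "BlockOutOfBounds",
                    f"reading {i} block rows {blk.first.row}-{blk.last.row}, "
                    f"cols {blk.first.col}-{blk.last.col} exceeds the "
                    f"{grid.n_rows}x{grid.n_cols} grid",
                )
            )


def validate_spec(spec: ParserSpec, grid) -> list[Finding]:
    """Check a spec against the grid it is meant to parse.

    Returns a list of findings (empty means valid): every reading block —
    stride-derived or explicit — must lie inside the grid, the block shape
    must agree with the well count and axis length for the chosen format,
    and axis labels (explicit or from_grid) must match the axis dimension.
    Findings are returned, never raised, so a caller can report all
    problems at once.
    """
    findings: list[Finding] = []
    wells = spec.wells.wells()

    if spec.data_format == "matrix":
        pr, pc = spec.wells.plate_rows, spec.wells.plate_cols
        if (spec.first_block.n_rows, spec.first_block.n_cols) != (pr, pc):
            findings.append(
                Finding(
                    "WellCountMismatch",
                    f"matrix block is {spec.first_block.n_rows}x{spec.first_block.n_cols} "
                    f"but the plate is {pr}x{pc}; the block must mimic the plate",
                )
            )
    else:
        expected = len(wells)
        actual = spec.well_axis_length
        if actual != expected:
            axis_word = "columns" if spec.data_format == "horizontal" else "rows"
            findings.append(
                Finding(
                    "WellCountMismatch",
                    f"{spec.data_format} block spans {actual} {axis_word} but the "
                    f"well layout lists {expected} wells",
                )
            )
        if spec.data_type == "single" and spec.axis_length != 1:
            findings.append(
                Finding(
                    "AxisLengthMismatch",
                    f"data_type=single requires a block one "
                    f"{'row' if spec.data_format == 'horizontal' else 'column'} "
                    f"thick along the reading axis, got {spec.axis_length}",
                )
            )

    from .extraction import locate_reading_blocks  # cycle-free at call time

    try:
        blocks = locate_reading_blocks(spec, grid=None)
    except Exception:  # pragma: no cover - geometry errors caught above
        blocks = [spec.first_block]
    _block_findings(blocks, grid, findings)

    if spec.axis is not None:
        ax = spec.axis
        if ax.mode == "explicit" and len(ax.values) != spec.axis_length:
            findings.append(
                Finding(
                    "AxisLengthMismatch",
                    f"axis.values has {len(ax.values)} labels but the block implies "
                    f"{spec.axis_length} {spec.axis_name} points",
                )
            )
        elif ax.mode == "from_grid":
            ref = ax.ref
            if ref.last.row > grid.n_rows or ref.last.col > grid.n_cols:
                findings.append(
                    Finding(
                        "AxisRefOutOfBounds",
                        f"axis.ref rows {ref.first.row}-{ref.last.row}, cols "
                        f"{ref.first.col}-{ref.last.col} exceeds the "
                        f"{grid.n_rows}x{grid.n_cols} grid",
                    )
                )
            n_labels = max(ref.n_rows, ref.n_cols)
            if n_labels != spec.axis_length:
                findings.append(
                    Finding(
                        "AxisLengthMismatch",
                        f"axis.ref covers {n_labels} cells but the block implies "
                        f"{spec.axis_length} {spec.axis_name} points",
                    )
                )
    return findings


# -- serialization ---------------------------------------------------------


def _cellref_to_json(ref: CellRef) -> dict:
    return {"row": ref.row, "col": ref.col}


def _block_to_json(blk: BlockRange) -> dict:
    return {"first": _cellref_to_json(blk.first), "last": _cellref_to_json(blk.last)}


def spec_to_dict(spec: ParserSpec) -> dict:
    """Plain-JSON representation of a spec (schema version included)."""
    doc: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "data_format": spec.data_format,
        "data_type": spec.data_type,
        "first_block": _block_to_json(spec.first_block),
        "num_readings": spec.num_readings,
        "reading_names": list(spec.reading_names),
    }
    if spec.block_stride is not None:
        doc["block_stride"] = spec.block_stride
    if spec.explicit_blocks is not None:
        doc["explicit_blocks"] = [_block_to_json(b) for b in spec.explicit_blocks]
    if spec.wells.mode == "plate":
        doc["wells"] = {
            "mode": "plate",
            "plate_rows": spec.wells.plate_rows,
            "plate_cols": spec.wells.plate_cols,
        }
    else:
        doc["wells"] = {"mode": "explicit", "well_ids": list(spec.wells.well_ids)}
    if spec.axis is not None:
        ax: dict[str, Any] = {"mode": spec.axis.mode}
        if spec.axis.values is not None:
            ax["values"] = list(spec.axis.values)
        if spec.axis.ref is not None:
            ax["ref"] = _block_to_json(spec.axis.ref)
        if spec.axis.start is not None:
            ax["start"] = spec.axis.start
        if spec.axis.step is not None:
            ax["step"] = spec.axis.step
        doc["axis"] = ax
    doc["sentinel_values"] = list(spec.sentinel_values)
    if spec.dialect is not None:
        doc["dialect"] = spec.dialect
    if spec.sheet is not None:
        doc["sheet"] = spec.sheet
    if spec.delimiter is not None:
        doc["delimiter"] = spec.delimiter
    return doc


def _require(doc: Mapping, key: str, path: str):
    if key not in doc:
        raise SpecSchemaError(f"missing required field {path}{key}")
    return doc[key]


def _check_unknown(doc: Mapping, allowed: set[str], path: str):
    unknown = set(doc) - allowed
    if unknown:
        raise SpecSchemaError(
            f"unknown field(s) {sorted(unknown)} at {path or '(top level)'}; "
            f"allowed: {sorted(allowed)}"
        )


def _parse_cellref(obj, path: str) -> CellRef:
    if isinstance(obj, str):
        try:
            return CellRef.from_a1(obj)
        except SpecSchemaError as exc:
            raise SpecSchemaError(f"{path}: {exc}") from None
    if isinstance(obj, Mapping):
        _check_unknown(obj, {"row", "col"}, path)
        row = _require(obj, "row", path + ".")
        col = _require(obj, "col", path + ".")
        if not isinstance(row, int) or not isinstance(col, int):
            raise SpecSchemaError(f"{path}.row/.col must be integers")
        return CellRef(row, col)
    raise SpecSchemaError(
        f'{path} must be {{"row": r, "col": c}} or a spreadsheet reference like "C7"'
    )


def _parse_block(obj, path: str) -> BlockRange:
    if not isinstance(obj, Mapping):
        raise SpecSchemaError(f"{path} must be an object with 'first' and 'last'")
    _check_unknown(obj, {"first", "last"}, path)
    first = _parse_cellref(_require(obj, "first", path + "."), path + ".first")
    last = _parse_cellref(_require(obj, "last", path + "."), path + ".last")
    try:
        return BlockRange(first, last)
    except SpecSchemaError as exc:
        raise SpecSchemaError(f"{path}: {exc}") from None


_TOP_LEVEL_KEYS = {
    "schema_version",
    "data_format",
    "data_type",
    "first_block",
    "num_readings",
    "reading_names",
    "block_stride",
    "explicit_blocks",
    "wells",
    "axis",
    "sentinel_values",
    "dialect",
    "sheet",
    "delimiter",
}


def spec_from_dict(doc: Mapping) -> ParserSpec:
    """Build a :class:`ParserSpec` from a parsed JSON/YAML document.

    Rejects unknown fields and wrong schema versions with messages citing
    the JSON path, so hand-edited spec files fail loudly and precisely.
    """
    if not isinstance(doc, Mapping):
        raise SpecSchemaError("spec document must be a JSON object")
    _check_unknown(doc, _TOP_LEVEL_KEYS, "")
    version = _require(doc, "schema_version", "")
    if version != SCHEMA_VERSION:
        raise SpecSchemaError(
            f"schema_version {version!r} is not supported; this build reads "
            f"version {SCHEMA_VERSION}"
        )
    data_format = _require(doc, "data_format", "")
    if data_format not in DATA_FORMATS:
        raise SpecSchemaError(
            f"data_format {data_format!r} is invalid; allowed values: {list(DATA_FORMATS)}"
        )
    data_type = _require(doc, "data_type", "")
    if data_type not in DATA_TYPES:
        raise SpecSchemaError(
            f"data_type {data_type!r} is invalid; allowed values: {list(DATA_TYPES)}"
        )
    first_block = _parse_block(_require(doc, "first_block", ""), "first_block")
    num_readings = _require(doc, "num_readings", "")
    if not isinstance(num_readings, int) or num_readings < 1:
        raise SpecSchemaError(f"num_readings must be a positive integer, got {num_readings!r}")
    reading_names = _require(doc, "reading_names", "")
    if not isinstance(reading_names, Sequence) or isinstance(reading_names, str):
        raise SpecSchemaError("reading_names must be a list of strings")

    explicit_blocks = None
    if "explicit_blocks" in doc:
        raw_blocks = doc["explicit_blocks"]
        if not isinstance(raw_blocks, Sequence):
            raise SpecSchemaError("explicit_blocks must be a list of block ranges")
        explicit_blocks = tuple(
            _parse_block(b, f"explicit_blocks[{i}]") for i, b in enumerate(raw_blocks)
        )

    wells_doc = _require(doc, "wells", "")
    if not isinstance(wells_doc, Mapping):
        raise SpecSchemaError("wells must be an object")
    _check_unknown(wells_doc, {"mode", "plate_rows", "plate_cols", "well_ids"}, "wells")
    mode = _require(wells_doc, "mode", "wells.")
    if mode not in WELL_MODES:
        raise SpecSchemaError(
            f"wells.mode {mode!r} is invalid; allowed values: {list(WELL_MODES)}"
        )
    wells = WellLayout(
        mode=mode,
        plate_rows=wells_doc.get("plate_rows"),
        plate_cols=wells_doc.get("plate_cols"),
        well_ids=tuple(wells_doc["well_ids"]) if "well_ids" in wells_doc else None,
    )

    axis = None
    if "axis" in doc and doc["axis"] is not None:
        ax_doc = doc["axis"]
        if not isinstance(ax_doc, Mapping):
            raise SpecSchemaError("axis must be an object")
        _check_unknown(ax_doc, {"mode", "values", "ref", "start", "step"}, "axis")
        ax_mode = _require(ax_doc, "mode", "axis.")
        if ax_mode not in AXIS_MODES:
            raise SpecSchemaError(
                f"axis.mode {ax_mode!r} is invalid; allowed values: {list(AXIS_MODES)}"
            )
        axis = AxisLabels(
            mode=ax_mode,
            values=tuple(ax_doc["values"]) if "values" in ax_doc else None,
            ref=_parse_block(ax_doc["ref"], "axis.ref") if "ref" in ax_doc else None,
            start=ax_doc.get("start"),
            step=ax_doc.get("step"),
        )

    sentinels = doc.get("sentinel_values")
    sheet = doc.get("sheet")
    if sheet is not None and not isinstance(sheet, (str, int)):
        raise SpecSchemaError("sheet must be a sheet name or a 1-based index")
    return ParserSpec(
        data_format=data_format,
        data_type=data_type,
        first_block=first_block,
        num_readings=num_readings,
        reading_names=tuple(str(n) for n in reading_names),
        block_stride=doc.get("block_stride"),
        explicit_blocks=explicit_blocks,
        wells=wells,
        axis=axis,
        sentinel_values=tuple(sentinels) if sentinels is not None else DEFAULT_SENTINELS,
        dialect=doc.get("dialect"),
        sheet=sheet,
        delimiter=doc.get("delimiter"),
    )


def save_spec(spec: ParserSpec, path: str | Path) -> None:
    """Write a spec as a JSON document (YAML if the extension says so)."""
    path = Path(path)
    doc = spec_to_dict(spec)
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
    else:
        path.write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def load_spec(path: str | Path) -> ParserSpec:
    """Read a spec from a JSON (or YAML) file; inverse of :func:`save_spec`."""
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except FileNotFoundError:
        raise SpecSchemaError(f"spec file not found: {path}") from None
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        try:
            doc = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise SpecSchemaError(f"malformed YAML in {path}: {exc}") from exc
    else:
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise SpecSchemaError(f"malformed JSON in {path}: {exc}") from exc
    return spec_from_dict(doc)
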