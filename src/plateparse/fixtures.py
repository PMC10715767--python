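"""Synthetic instrument-style exports with known ground truth.

Real plate readers export measurements buried in idiosyncratic furniture:
date stamps, protocol names, per-block labels, embedded plate row/column
headers, blank separator rows. The generator fabricates such files — in all
five accepted dialects — together with the parser spec that locates the
data, a metadata table, and the exact joined table the engine must
reproduce. Fixtures are pure functions of their style (seed included), so
the same style always yields byte-identical files.

Decoration layouts imitate generic export furniture; they do not copy any
vendor's proprietary format.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidStyle
from .raw_io import CellGrid, MetadataTable, metadata_from_grid, write_grid
from .spec_model import (
    AxisLabels,
    BlockRange,
    CellRef,
    ParserSpec,
    WellLayout,
    save_spec,
)
from .wells import enumerate_wells

# (name, low, high, decimals) — plausible instrument ranges; values are
# cosmetic, never interpreted.
_READING_PROFILES = (
    ("OD600", 0.03, 1.8, 4),
    ("GFP", 10.0, 48000.0, 1),
    ("mCherry", 5.0, 21000.0, 1),
    ("OD700", 0.02, 1.5, 4),
)

_SENTINEL_TOKENS = ("OVRFLW", "NA", "OVER")

_EXTENSIONS = {"csv": ".csv", "csv2": ".csv", "tsv": ".tsv", "txt": ".txt", "excel": ".xlsx"}


@dataclass(frozen=True)
class FixtureStyle:
    """Everything that determines one synthetic export, deterministically.

    ``decorated`` adds preamble lines, per-block labels/headers and (matrix)
    embedded plate headers with blank separators, so stride exceeds the
    block height. ``axis_mode`` picks where the spec's time/wavelength
    labels come from; ``from_grid`` requires a decorated layout because only
    decorated files carry a label row/column. ``metadata_coverage`` below 1
    drops trailing wells from the metadata file to exercise the join's
    unmatched-well path. ``sentinel_rate`` injects overflow markers.
    """

    name: str
    data_format: str
    data_type: str = "single"
    plate_rows: int = 8
    plate_cols: int = 12
    num_readings: int = 1
    axis_len: int = 1
    decorated: bool = False
    axis_mode: str = "uniform"
    wells_mode: str = "plate"
    sentinel_rate: float = 0.0
    metadata_coverage: float = 1.0
    dialect: str = "csv"
    seed: int = 0

    def __post_init__(self):
        if self.data_format not in ("horizontal", "vertical", "matrix"):
            raise InvalidStyle(f"unknown data_format {self.data_format!r}")
        if self.data_type not in ("single", "timecourse", "spectrum"):
            raise InvalidStyle(f"unknown data_type {self.data_type!r}")
        if self.dialect not in _EXTENSIONS:
            raise InvalidStyle(f"unknown dialect {self.dialect!r}")
        if self.data_format == "matrix" and self.data_type != "single":
            raise InvalidStyle(
                "matrix format carries one value per well per block; "
                f"data_type={self.data_type!r} conflicts with data_format='matrix'"
            )
        if self.data_format == "matrix" and self.wells_mode != "plate":
            raise InvalidStyle("matrix format requires wells_mode='plate'")
        if self.data_type == "single" and self.axis_len != 1:
            raise InvalidStyle(
                f"data_type='single' implies axis_len=1, got {self.axis_len}"
            )
        if self.data_type != "single" and self.axis_len < 2:
            raise InvalidStyle(
                f"data_type={self.data_type!r} needs axis_len >= 2, got {self.axis_len}"
            )
        if self.axis_mode == "from_grid" and not self.decorated:
            raise InvalidStyle(
                "axis_mode='from_grid' needs a decorated layout (plain files "
                "carry no label row)"
            )
        if not 0 <= self.sentinel_rate < 1:
            raise InvalidStyle(f"sentinel_rate must be in [0, 1), got {self.sentinel_rate}")
        if not 0 < self.metadata_coverage <= 1:
            raise InvalidStyle(
                f"metadata_coverage must be in (0, 1], got {self.metadata_coverage}"
            )
        if self.num_readings < 1 or self.num_readings > len(_READING_PROFILES):
            raise InvalidStyle(
                f"num_readings must be 1..{len(_READING_PROFILES)}, got {self.num_readings}"
            )


@dataclass(frozen=True)
class FixtureBundle:
    """One synthetic export plus everything needed to parse and check it."""

    style: FixtureStyle
    grid_rows: tuple[tuple[str, ...], ...]
    spec: ParserSpec
    metadata_rows: tuple[tuple[str, ...], ...]
    truth: pd.DataFrame

    def grid(self) -> CellGrid:
        """The raw file as an in-memory grid (no disk round trip)."""
        return CellGrid.from_rows(self.grid_rows, source_dialect=self.style.dialect)

    def metadata(self) -> MetadataTable:
        return metadata_from_grid(CellGrid.from_rows(self.metadata_rows))

    @property
    def raw_extension(self) -> str:
        return _EXTENSIONS[self.style.dialect]

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Write raw file, spec JSON, metadata CSV and truth CSV; returns paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "raw": directory / f"{self.style.name}{self.raw_extension}",
            "spec": directory / f"{self.style.name}.parser.json",
            "metadata": directory / f"{self.style.name}.metadata.csv",
            "truth": directory / f"{self.style.name}.truth.csv",
        }
        write_grid(self.grid_rows, paths["raw"], dialect=self.style.dialect)
        save_spec(self.spec, paths["spec"])
        write_grid(self.metadata_rows, paths["metadata"], dialect="csv")
        self.truth.to_csv(paths["truth"], index=False)
        return paths


def _format_value(value: float, decimals: int, dialect: str) -> str:
    text = f"{value:.{decimals}f}"
    return text.replace(".", ",") if dialect == "csv2" else text


def _axis_labels(style: FixtureStyle) -> tuple[list[int], int, int]:
    """(labels, start, step): seconds for timecourses, nm for spectra."""
    if style.data_type == "timecourse":
        start, step = 0, 300
    else:
        start, step = 350, 10
    return [start + i * step for i in range(style.axis_len)], start, step


def _fixture_wells(style: FixtureStyle) -> list[str]:
    all_wells = enumerate_wells(style.plate_rows, style.plate_cols)
    if style.wells_mode == "explicit":
        return all_wells[::2]  # non-contiguous selection, deliberately
    return all_wells


def generate_fixture(style: FixtureStyle) -> FixtureBundle:
    """Fabricate the raw grid, matching spec, metadata, and joined truth."""
    rng = np.random.default_rng(style.seed)
    wells = _fixture_wells(style)
    n_wells = len(wells)
    axis_len = style.axis_len
    profiles = _READING_PROFILES[: style.num_readings]
    reading_names = tuple(p[0] for p in profiles)

    # texts[i][t][w] is the written cell text; floats[i][t][w] the truth
    # (nan where a sentinel was injected).
    texts: list[list[list[str]]] = []
    floats: list[list[list[float]]] = []
    for name, lo, hi, dec in profiles:
        raw = rng.uniform(lo, hi, size=(axis_len, n_wells))
        t_rows, f_rows = [], []
        for t in range(axis_len):
            t_row, f_row = [], []
            for w in range(n_wells):
                if style.sentinel_rate and rng.random() < style.sentinel_rate:
                    t_row.append(str(rng.choice(_SENTINEL_TOKENS)))
                    f_row.append(math.nan)
                else:
                    text = _format_value(raw[t, w], dec, style.dialect)
                    t_row.append(text)
                    f_row.append(float(text.replace(",", ".")))
            t_rows.append(t_row)
            f_rows.append(f_row)
        texts.append(t_rows)
        floats.append(f_rows)

    labels, ax_start, ax_step = _axis_labels(style)
    builder = {
        "horizontal": _build_horizontal,
        "vertical": _build_vertical,
        "matrix": _build_matrix,
    }[style.data_format]
    rows, first_block, stride, axis_ref = builder(style, wells, texts, labels)

    axis = None
    if style.data_type != "single":
        if style.axis_mode == "explicit":
            axis = AxisLabels(mode="explicit", values=tuple(labels))
        elif style.axis_mode == "uniform":
            axis = AxisLabels(mode="uniform", start=ax_start, step=ax_step)
        else:
            axis = AxisLabels(mode="from_grid", ref=axis_ref)

    if style.wells_mode == "plate":
        layout = WellLayout(
            mode="plate", plate_rows=style.plate_rows, plate_cols=style.plate_cols
        )
    else:
        layout = WellLayout(mode="explicit", well_ids=tuple(wells))

    spec = ParserSpec(
        data_format=style.data_format,
        data_type=style.data_type,
        first_block=first_block,
        num_readings=style.num_readings,
        reading_names=reading_names,
        block_stride=stride,
        wells=layout,
        axis=axis,
        dialect=style.dialect,
    )

    # Metadata: strain/inducer annotations, optionally incomplete.
    n_meta = max(1, int(round(style.metadata_coverage * n_wells)))
    inducers = [int(rng.choice([0, 1, 10, 100])) for _ in range(n_meta)]
    metadata_rows = [("well", "strain", "inducer_uM")] + [
        (wells[i], f"S{i % 6 + 1}", str(inducers[i])) for i in range(n_meta)
    ]
    meta_map = {wells[i]: (f"S{i % 6 + 1}", inducers[i]) for i in range(n_meta)}

    truth = _build_truth(style, wells, reading_names, floats, labels, meta_map)
    return FixtureBundle(
        style=style,
        grid_rows=tuple(tuple(r) for r in rows),
        spec=spec,
        metadata_rows=tuple(tuple(r) for r in metadata_rows),
        truth=truth,
    )


def _build_truth(style, wells, reading_names, floats, labels, meta_map):
    complete = len(meta_map) == len(wells)
    cols: dict = {"well": [], "strain": [], "inducer_uM": []}
    axis_name = {"timecourse": "time", "spectrum": "wavelength"}.get(style.data_type)
    if axis_name:
        cols[axis_name] = []
    for name in reading_names:
        cols[name] = []
    for w_idx, w in enumerate(wells):
        strain, inducer = meta_map.get(w, (math.nan, math.nan))
        for t in range(style.axis_len):
            cols["well"].append(w)
            cols["strain"].append(strain)
            cols["inducer_uM"].append(inducer)
            if axis_name:
                cols[axis_name].append(labels[t])
            for i, name in enumerate(reading_names):
                cols[name].append(floats[i][t][w_idx])
    truth = pd.DataFrame(cols)
    if complete:
        truth["inducer_uM"] = truth["inducer_uM"].astype(int)
    return truth


# -- layout builders --------------------------------------------------------
# Each returns (rows, first_block, stride, axis_ref). Coordinates follow
# directly from the decoration counts, so tests can recompute them
# independently.


def _build_horizontal(style, wells, texts, labels):
    n_wells = len(wells)
    axis_len = style.axis_len
    has_axis = style.data_type != "single"
    if not style.decorated:
        rows = [list(texts[i][t]) for i in range(style.num_readings) for t in range(axis_len)]
        first_block = BlockRange(CellRef(1, 1), CellRef(axis_len, n_wells))
        return rows, first_block, axis_len, None

    corner = {"timecourse": "Time [s]", "spectrum": "Wavelength [nm]"}.get(
        style.data_type, "Well"
    )
    rows: list[list[str]] = [
        ["Date: 2024-05-14"],
        ["Protocol: synthetic kinetic export"],
        [],
        [corner] + list(wells),
    ]
    for i in range(style.num_readings):
        rows.append([f"Reading: {_READING_PROFILES[i][0]}"])
        for t in range(axis_len):
            lead = str(labels[t]) if has_axis else ""
            rows.append([lead] + list(texts[i][t]))
    rows.append(["End of data"])
    # preamble 3 + well header 1 + reading label 1 => data starts at row 6
    first_block = BlockRange(CellRef(6, 2), CellRef(5 + axis_len, 1 + n_wells))
    axis_ref = BlockRange(CellRef(6, 1), CellRef(5 + axis_len, 1)) if has_axis else None
    return rows, first_block, axis_len + 1, axis_ref


def _build_vertical(style, wells, texts, labels):
    n_wells = len(wells)
    axis_len = style.axis_len
    has_axis = style.data_type != "single"
    if not style.decorated:
        rows = [
            [texts[i][t][w] for i in range(style.num_readings) for t in range(axis_len)]
            for w in range(n_wells)
        ]
        first_block = BlockRange(CellRef(1, 1), CellRef(n_wells, axis_len))
        return rows, first_block, axis_len, None

    rows = [["Export: synthetic vertical layout"], []]
    header = ["Well"]
    for i in range(style.num_readings):
        header += [_READING_PROFILES[i][0]] + [""] * (axis_len - 1)
        if i < style.num_readings - 1:
            header.append("")  # spacer column
    rows.append(header)
    data_start = 4
    if has_axis:
        sub = [""]
        for i in range(style.num_readings):
            sub += [str(lab) for lab in labels]
            if i < style.num_readings - 1:
                sub.append("")
        rows.append(sub)
        data_start = 5
    for w in range(n_wells):
        line = [wells[w]]
        for i in range(style.num_readings):
            line += [texts[i][t][w] for t in range(axis_len)]
            if i < style.num_readings - 1:
                line.append("")
        rows.append(line)
    first_block = BlockRange(
        CellRef(data_start, 2), CellRef(data_start + n_wells - 1, 1 + axis_len)
    )
    axis_ref = (
        BlockRange(CellRef(data_start - 1, 2), CellRef(data_start - 1, 1 + axis_len))
        if has_axis
        else None
    )
    return rows, first_block, axis_len + 1, axis_ref


def _build_matrix(style, wells, texts, labels):
    pr, pc = style.plate_rows, style.plate_cols
    letters = [chr(ord("A") + r) for r in range(pr)]
    if not style.decorated:
        rows = []
        for i in range(style.num_readings):
            for r in range(pr):
                rows.append([texts[i][0][r * pc + c] for c in range(pc)])
        first_block = BlockRange(CellRef(1, 1), CellRef(pr, pc))
        return rows, first_block, pr, None

    rows = [["Instrument: synthetic matrix export"], []]
    for i in range(style.num_readings):
        rows.append([_READING_PROFILES[i][0]])
        rows.append([""] + [str(c + 1) for c in range(pc)])
        for r in range(pr):
            rows.append([letters[r]] + [texts[i][0][r * pc + c] for c in range(pc)])
        if i < style.num_readings - 1:
            rows.append([])  # blank separator between plate grids
    # preamble 2 + reading label 1 + column header 1 => data starts at row 5
    first_block = BlockRange(CellRef(5, 2), CellRef(4 + pr, 1 + pc))
    return rows, first_block, pr + 3, None


# -- catalog -----------------------------------------------------------------


def style_catalog() -> list[FixtureStyle]:
    """Named, seeded styles covering format x type x decoration x dialect.

    The catalog spans every feasible combination of layout and data type
    (matrix carries single readings only), both plain and decorated
    furniture, all five dialects, all three axis-label modes, sentinel
    injection, an explicit (non-contiguous) well selection, incomplete
    metadata, and 6-, 96- and 384-well plates.
    """
    S = FixtureStyle
    return [
        S("horizontal-single-plain-csv", "horizontal", "single",
          num_readings=2, dialect="csv", seed=101),
        S("horizontal-single-decorated-tsv", "horizontal", "single",
          num_readings=3, decorated=True, dialect="tsv", seed=102),
        S("horizontal-timecourse-plain-txt", "horizontal", "timecourse",
          num_readings=2, axis_len=5, axis_mode="uniform", dialect="txt", seed=103),
        S("horizontal-timecourse-decorated-excel", "horizontal", "timecourse",
          num_readings=2, axis_len=5, decorated=True, axis_mode="from_grid",
          dialect="excel", seed=104),
        S("horizontal-spectrum-plain-csv2", "horizontal", "spectrum",
          axis_len=11, axis_mode="explicit", dialect="csv2", seed=105),
        S("horizontal-spectrum-decorated-csv", "horizontal", "spectrum",
          axis_len=21, decorated=True, axis_mode="from_grid", dialect="csv", seed=106),
        S("vertical-single-plain-tsv", "vertical", "single",
          num_readings=2, dialect="tsv", seed=107),
        S("vertical-single-decorated-txt", "vertical", "single",
          num_readings=3, decorated=True, dialect="txt", seed=108),
        S("vertical-timecourse-plain-excel", "vertical", "timecourse",
          num_readings=2, axis_len=6, axis_mode="explicit", dialect="excel", seed=109),
        S("vertical-timecourse-decorated-csv2", "vertical", "timecourse",
          num_readings=2, axis_len=4, decorated=True, axis_mode="from_grid",
          dialect="csv2", seed=110),
        S("vertical-spectrum-plain-csv", "vertical", "spectrum",
          axis_len=16, axis_mode="uniform", dialect="csv", seed=111),
        S("vertical-spectrum-decorated-tsv", "vertical", "spectrum",
          axis_len=9, decorated=True, axis_mode="from_grid", dialect="tsv", seed=112),
        S("matrix-single-plain-txt", "matrix", "single",
          num_readings=2, dialect="txt", seed=113),
        S("matrix-single-decorated-excel", "matrix", "single",
          num_readings=3, decorated=True, dialect="excel", seed=114),
        S("matrix-single-decorated-csv2", "matrix", "single",
          num_readings=2, decorated=True, dialect="csv2", seed=115),
        S("horizontal-single-decorated-384-csv", "horizontal", "single",
          plate_rows=16, plate_cols=24, num_readings=2, decorated=True,
          dialect="csv", seed=116),
        S("vertical-timecourse-sentinels-csv", "vertical", "timecourse",
          num_readings=2, axis_len=5, sentinel_rate=0.05, axis_mode="uniform",
          dialect="csv", seed=117),
        S("matrix-single-sentinels-decorated-tsv", "matrix", "single",
          num_readings=2, decorated=True, sentinel_rate=0.04, dialect="tsv", seed=118),
        S("horizontal-timecourse-explicit-wells-csv", "horizontal", "timecourse",
          axis_len=4, wells_mode="explicit", axis_mode="explicit",
          dialect="csv", seed=119),
        S("vertical-single-partial-metadata-csv", "vertical", "single",
          num_readings=2, metadata_coverage=0.9, dialect="csv", seed=120),
        S("horizontal-spectrum-decorated-csv2", "horizontal", "spectrum",
          axis_len=13, decorated=True, axis_mode="from_grid", dialect="csv2", seed=121),
        S("matrix-single-plain-excel", "matrix", "single",
          num_readings=2, dialect="excel", seed=122),
        S("vertical-spectrum-decorated-excel", "vertical", "spectrum",
          num_readings=2, axis_len=7, decorated=True, axis_mode="explicit",
          dialect="excel", seed=123),
        S("horizontal-timecourse-decorated-6well-csv", "horizontal", "timecourse",
          plate_rows=2, plate_cols=3, num_readings=2, axis_len=4, decorated=True,
          axis_mode="uniform", dialect="csv", seed=124),
    ]


def get_style(name: str) -> FixtureStyle:
    for style in style_catalog():
        if style.name == name:
            return style
    raise InvalidStyle(
        f"no catalog style named {name!r}; available: "
        + ", ".join(s.name for s in style_catalog())
    )
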