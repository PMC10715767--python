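# plateparse

Declarative, position-based parsing of multiwell plate reader exports into
tidy, metadata-joined tables.

## The problem

Plate readers — the workhorse instruments that measure absorbance,
fluorescence and luminescence across 6- to 384-well plates — export their
data in vendor-specific layouts with the measurements buried between date
stamps, protocol banners and embedded plate headers. Downstream analysis
packages (growth-curve fitting, fluorescent protein quantification,
screening statistics) expect the opposite: tidy tables, one observation per
row, with experimental metadata attached. Every lab therefore ends up
writing one-off parser scripts per instrument and per export mode.

plateparse replaces those one-off scripts with a small, portable **parser
specification**: a JSON (or YAML) file that describes *where* the data sits
in the raw file — purely by grid position — and how to interpret it. No
content sniffing, no instrument-specific heuristics: a cell is data because
the spec says so, nothing else in the file matters. Once written (or
generated with `plateparse init-spec`), a spec parses every future export
from the same instrument configuration.

## The model

A raw export is a rectangular grid of text cells with 1-based spreadsheet
coordinates. A spec declares:

- **data format** — `horizontal` (readings in rows, wells across columns),
  `vertical` (wells down rows, readings across columns), or `matrix`
  (an 8 × 12 block that visually mimics a 96-well plate);
- **data type** — `single` (one value per well), `timecourse` (kinetic
  series) or `spectrum` (wavelength sweep);
- **the first reading block** — the rectangle of the first measurement
  channel; further channels follow at a fixed *stride* (rows for
  horizontal/matrix, columns for vertical; default: immediately adjacent),
  or at explicitly listed rectangles for irregular exports;
- **the well layout** — a plate (`8 × 12` → `A1 … H12`, row-major) or an
  explicit well list;
- **the axis labels** — timepoints/wavelengths given literally, as an
  arithmetic sequence, or read from a labelled row/column of the grid;
- **sentinel tokens** (`OVRFLW`, `NA`, …) that become missing values, and
  dialect hints for reading the file.

The engine validates the spec against the grid (every problem reported at
once, with machine-readable codes), extracts and coerces the blocks, maps
cells to wells, reshapes to a long table (wide over readings), and joins
the user's metadata on the canonicalized `well` key — metadata columns on
the left, measurements on the right. Data rows are never lost: wells
missing from the metadata are kept with empty annotations and a warning.

Five raw dialects are accepted: CSV, CSV2 (semicolon separator with decimal
commas), TSV, tab-delimited `.txt` (separator overridable), and Excel
`.xlsx` workbooks.

## Worked example

The package ships a generator of instrument-style synthetic exports with
known ground truth (also the backbone of the test suite). Emit one and
parse it:

```bash
$ plateparse fixture --style horizontal-timecourse-plain-txt --out-dir demo
$ plateparse run \
    --parser demo/horizontal-timecourse-plain-txt.parser.json \
    --data demo/horizontal-timecourse-plain-txt.txt \
    --metadata demo/horizontal-timecourse-plain-txt.metadata.csv \
    --out demo/parsed.csv
parsed demo/horizontal-timecourse-plain-txt.txt
  format: horizontal / timecourse
  readings: OD600, GFP
  wells: 96, axis points: 5
  output rows: 480 -> demo/parsed.csv
```

The raw file holds two stacked 5 × 96 blocks — five timepoints down the
rows, 96 wells across the columns, one block per channel. The output is
tidy: 96 wells × 5 timepoints = 480 rows, one column per reading, with the
strain/inducer metadata joined on `well`:

```
well,strain,inducer_uM,time,OD600,GFP
A1,S1,10,0,0.5834,10280.5
A1,S1,10,300,1.5873,27668.4
A1,S1,10,600,1.5391,13309.4
```

`OD600` is culture optical density (dimensionless), `GFP` fluorescence in
arbitrary units, `time` in seconds — ready for any tidy-data analysis tool.

The same from Python:

```python
from plateparse import parse_files

table, warnings, spec, grid = parse_files(
    "demo/horizontal-timecourse-plain-txt.parser.json",
    "demo/horizontal-timecourse-plain-txt.txt",
    "demo/horizontal-timecourse-plain-txt.metadata.csv",
)
```

Other subcommands: `plateparse validate` checks a spec against a file
without extracting; `plateparse init-spec` writes a spec from flags;
`plateparse fixture --list` names all synthetic export styles.

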