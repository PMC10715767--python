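# Methods

## Positional extraction model

plateparse treats a raw export as nothing more than a rectangular grid of
text cells, addressed 1-based from the top-left exactly as a spreadsheet
program displays the file — no header inference, no row skipping, no type
guessing at read time. A parser spec names rectangles inside that grid; the
engine's one structural guarantee is that *only* cells inside the named
rectangles (reading blocks, plus the axis label range when labels are read
from the grid) influence the output. This is deliberately the opposite of
content-sniffing parsers: it trades automation for universality, because a
rectangle can be pointed at in any export format, while context clues are
instrument-specific. The property is enforced operationally by a fuzz test
that perturbs out-of-block cells and asserts bit-identical extraction.

## Layout conventions

Three layout conventions cover the instruments in scope:

- **horizontal** — wells across columns in row-major plate order
  (`A1, A2, …`), one row per time/wavelength point;
- **vertical** — the transpose: wells down rows, axis across columns;
- **matrix** — one plate-shaped block (8 × 12 for a 96-well plate), cell
  (r, c) belonging to the well at plate position (r, c). Matrix blocks hold
  a single value per well; a matrix timecourse is expressed as one reading
  per timepoint via stride or explicit blocks.

Readings after the first are placed by a **stride** between block starts:
rows for horizontal/matrix, columns for vertical, defaulting to the block's
own extent (immediately adjacent blocks — the dominant convention in real
exports). Decorated exports, where labels or blank lines separate blocks,
set a larger stride; genuinely irregular exports list every rectangle with
`explicit_blocks`. The first block must enclose data cells only; embedded
plate row/column headers are decoration that the stride absorbs.

Timecourse orientation follows from the well-axis definitions: horizontal
puts time down the rows, vertical puts it across the columns. The
transpose-duality test (the same measurements exported both ways parse to
identical tables) pins this down.

## Parameters and defaults

- **Well layout**: plate mode generates row letters A–Z (≤ 26 rows; no
  `AA` convention is invented — no plate in scope exceeds 384 wells)
  crossed with 1-based column numbers, no zero padding. Well ids are
  canonicalized everywhere (`a01` → `A1`), and canonicalization is
  idempotent.
- **Sentinels**: `"", NA, OVRFLW, OVER, Overflow, ?` case-insensitive by
  default, fully overridable per spec. Sentinel cells become missing values
  (never zero) and propagate as empty fields in the output CSV.
- **Dialects**: `csv` (RFC 4180 quoting), `csv2` (semicolon separator,
  decimal comma — never auto-inferred because it shares the `.csv`
  extension), `tsv`, `txt` (tab by default, `--delimiter` overridable),
  `excel` (`.xlsx`; first sheet by default, `--sheet` takes a name or
  1-based index). Legacy `.xls` workbooks are rejected with a pointer to
  convert. Text files are decoded as UTF-8 with a logged latin-1 fallback.
- **Axis labels**: `explicit` list, `uniform` arithmetic sequence
  (start/step; seconds or nanometres by the user's convention — no unit
  conversion is attempted), or `from_grid` (a single row/column of cells,
  coerced to numbers when every label parses, otherwise kept as text so
  that `"0 s", "30 s"` rows survive).
- **Spec files**: JSON with a `schema_version` field; YAML accepted as a
  convenience superset; spreadsheet-style cell references (`"B5"`)
  accepted on load. Unknown fields and foreign schema versions are rejected
  with messages citing the JSON path — hand-edited files fail loudly.

## Output schema

The tidy table is long over wells (and over the axis, well-major) and wide
over readings, with the axis column fixed to `time` (timecourse) or
`wavelength` (spectrum) — renamable via `--axis-name` for downstream-tool
compatibility. Joining is driven by the data rows: measurements are never
dropped because annotations are incomplete; unmatched wells on either side
produce warnings naming them exactly. Output columns are the metadata
columns (well first, then file order) followed by axis and reading columns.
Numbers are written at full precision so a re-read reproduces them exactly.

## The synthetic export generator

No public corpus of raw plate-reader exports exists, so the test oracle is
a generator that fabricates them. A style (layout × data type × plate size
× readings × axis length × decoration × dialect × seed) deterministically
produces a bundle: the raw file, the spec whose coordinates point at the
true blocks, a metadata table, and the exact joined table the engine must
reproduce. Decoration profiles imitate generic export furniture — date and
protocol preambles, per-block labels, embedded plate headers, blank
separators — without copying any vendor's proprietary layout; measurement
values are uniform draws in plausible instrument ranges (e.g. 0.03–1.8 for
absorbance-like channels) and are purely cosmetic, since the engine never
interprets them.

The catalog of 24 named styles covers the full feasible cross product of
layout × data type × plain/decorated, all five dialects, all three
axis-label modes, sentinel injection, a non-contiguous explicit well
selection, incomplete metadata, and 6-, 96- and 384-well plates.

What passing the catalog does and does not show: the generator reproduces
the *structural* diversity of real exports (block placement, decoration,
dialect, missing-value markers), so the round trips demonstrate that the
positional engine recovers ground truth whenever the spec's coordinates are
correct. It does not demonstrate coverage of any specific commercial
instrument's format, nor robustness to a spec pointing at the wrong cells —
the validation layer catches shape mismatches, but a wrong-but-shape-
consistent rectangle is extracted as specified. That is inherent to the
positional design.

## Numerical and degenerate-input choices

Coercion strips whitespace, maps sentinels to missing, converts the decimal
comma (with thousands-separator periods removed) only for csv2 sources, and
parses the rest as floats; every non-numeric cell in a block is collected
and reported at once with its grid coordinates. Short rows are right-padded
with empty strings at read time so grids are always rectangular; an empty
metadata file, duplicate wells after canonicalization, and out-of-range
Excel sheets are all typed errors with stable CLI exit codes. Validation
returns the complete list of findings rather than failing on the first.

## Problem sizes

The test suite and the acceptance script run the full 24-style catalog end
to end (disk round trips in every dialect), 200 positional perturbations
per style in the suite (50 in the script), 500 randomized spec
serialization round trips, and plates up to 384 wells with spectra up to
21 wavelengths — sizes chosen to exercise every code path while keeping a
full run in the tens of seconds on one CPU; real exports are of the same
order, since a plate file rarely exceeds a few thousand cells.

## Known limitations

- No heuristic location of data: a spec must be authored per export format
  (that is the design stance, not an omission).
- Legacy `.xls` is not read; sheets must be converted to `.xlsx` or text.
- csv vs csv2 cannot be auto-detected; csv2 is an explicit flag.
- Plate rows beyond `Z` (hypothetical > 26-row plates) are unsupported.
- No downstream analytics (growth rates, calibration, normalization) —
  the output is the input to such tools.
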