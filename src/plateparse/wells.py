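"""Well identifier utilities: enumeration and canonicalization.

A well identifier is a row letter followed by a 1-based column number,
``A1`` .. ``H12`` on the standard 96-well plate. Plates are limited to 26
rows (single letters A-Z); no real plate in scope exceeds 384 wells (P24).
"""

from __future__ import annotations

import re
import string

from .errors import MalformedWell, UnsupportedPlate

_WELL_RE = re.compile(r"^([A-Za-z])0*([1-9][0-9]*)$")


def enumerate_wells(plate_rows: int, plate_cols: int) -> list[str]:
    """Row-major well identifiers for a ``plate_rows`` x ``plate_cols`` plate.

    Rows are lettered A, B, ... and columns numbered from 1 with no zero
    padding, so an 8x12 plate yields ``["A1", "A2", ..., "H12"]`` — the
    order in which instruments typically list wells in horizontal and
    vertical exports.
    """
    if plate_rows < 1 or plate_cols < 1:
        raise UnsupportedPlate(
            f"plate dimensions must be positive, got {plate_rows}x{plate_cols}"
        )
    if plate_rows > 26:
        raise UnsupportedPlate(
            f"plates with more than 26 rows are unsupported (got {plate_rows}); "
            "row letters beyond 'Z' have no standard convention"
        )
    letters = string.ascii_uppercase[:plate_rows]
    return [f"{r}{c}" for r in letters for c in range(1, plate_cols + 1)]


def canonicalize_well(well: str) -> str:
    """Normalize a well identifier: strip whitespace, uppercase the row
    letter, drop leading zeros from the column number (``"a01"`` -> ``"A1"``).

    Idempotent; raises :class:`MalformedWell` if the input is not a single
    letter followed by digits.
    """
    s = str(well).strip()
    m = _WELL_RE.match(s)
    if m is None:
        raise MalformedWell(
            f"well identifier {well!r} is not a row letter followed by a column number"
        )
    return f"{m.group(1).upper()}{m.group(2)}"


def well_position(well: str) -> tuple[int, int]:
    """(row, col) 1-based plate position of a canonical well identifier."""
    w = canonicalize_well(well)
    return string.ascii_uppercase.index(w[0]) + 1, int(w[1:])
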