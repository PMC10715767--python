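"""Typed error taxonomy shared by every stage of the parsing pipeline.

Each error class carries a stable machine-readable ``code`` and maps to a
documented CLI exit code, so shell pipelines can branch on failure class.
Validation findings (non-throwing) live in :mod:`plateparse.spec_model`.
"""

from __future__ import annotations


class PlateParseError(Exception):
    """Base class for all typed errors raised by plateparse."""

    code = "PlateParseError"
    exit_code = 1


class FileUnreadable(PlateParseError):
    code = "FileUnreadable"
    exit_code = 10


class UnknownDialect(PlateParseError):
    code = "UnknownDialect"
    exit_code = 11


class SheetNotFound(PlateParseError):
    code = "SheetNotFound"
    exit_code = 12


class MissingWellColumn(PlateParseError):
    code = "MissingWellColumn"
    exit_code = 13


class DuplicateWell(PlateParseError):
    code = "DuplicateWell"
    exit_code = 14


class MalformedWell(PlateParseError):
    code = "MalformedWell"
    exit_code = 15


class UnsupportedPlate(PlateParseError):
    code = "UnsupportedPlate"
    exit_code = 16


class SpecSchemaError(PlateParseError):
    """Malformed or version-incompatible parser-spec document.

    The message cites the JSON path of the offending field.
    """

    code = "SpecSchemaError"
    exit_code = 17


class ValidationFailed(PlateParseError):
    """Raised by the CLI when validate_spec returns findings."""

    code = "ValidationFailed"
    exit_code = 18

    def __init__(self, findings):
        self.findings = list(findings)
        lines = "; ".join(f"{f.code}: {f.message}" for f in self.findings)
        super().__init__(f"{len(self.findings)} validation finding(s): {lines}")


class BlockOutOfBounds(PlateParseError):
    code = "BlockOutOfBounds"
    exit_code = 19


class NonNumericCell(PlateParseError):
    """A data-block cell that is neither numeric nor a sentinel.

    ``offenders`` lists every such cell as (row, col, text) in grid
    coordinates so the user can adjust the block selection.
    """

    code = "NonNumericCell"
    exit_code = 20

    def __init__(self, offenders):
        self.offenders = list(offenders)
        shown = ", ".join(f"({r},{c})={t!r}" for r, c, t in self.offenders[:10])
        more = "" if len(self.offenders) <= 10 else f" (+{len(self.offenders) - 10} more)"
        super().__init__(
            f"{len(self.offenders)} non-numeric cell(s) in data block: {shown}{more}"
        )


class DimensionMismatch(PlateParseError):
    code = "DimensionMismatch"
    exit_code = 21


class AxisLengthMismatch(PlateParseError):
    code = "AxisLengthMismatch"
    exit_code = 22


class InvalidStyle(PlateParseError):
    code = "InvalidStyle"
    exit_code = 23


class PathUnwritable(PlateParseError):
    code = "PathUnwritable"
    exit_code = 24
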