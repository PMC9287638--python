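"""Exception hierarchy and warning categories.

The CLI maps :class:`ValidationError` to exit code 1 and
:class:`FormatError` (malformed input files, bad usage) to exit code 2.
"""

from __future__ import annotations


class OriginsError(Exception):
    """Base class for all package errors."""


class ValidationError(OriginsError):
    """Input is well-formed but violates a contract (negative entries,
    empty result sets, inconsistent shapes...)."""


class FormatError(OriginsError):
    """Input file or stream cannot be parsed."""

    def __init__(self, message: str, *, line: int | None = None, path: str | None = None):
        self.line = line
        self.path = path
        prefix = ""
        if path is not None:
            prefix += f"{path}: "
        if line is not None:
            prefix += f"line {line}: "
        super().__init__(prefix + message)


class EmptyCatalogError(ValidationError):
    """A GO annotation parse matched zero rows — distinct from a parse failure."""


class DegenerateRangeWarning(UserWarning):
    """Min-max scaling hit a constant vector; output is all zeros."""


class DuplicateEdgeWarning(UserWarning):
    """An edge list contained the same unordered pair more than once."""
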