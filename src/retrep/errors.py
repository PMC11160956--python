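"""Exception hierarchy for retrep.

All retrep-specific failures derive from :class:`RetrepError` so callers
can catch one base class at pipeline boundaries.
"""


class RetrepError(Exception):
    """Base class for all retrep errors."""


class TableSchemaError(RetrepError):
    """A required column is missing or the table layout is unusable."""


class RecordValidationError(RetrepError):
    """A row or record violates a domain invariant (range, finiteness, parse)."""


class DegenerateCorrelationError(RetrepError):
    """Correlation undefined because one variable has zero variance."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(f"correlation undefined: column {column!r} has zero variance")


class AnalysisError(RetrepError):
    """An analysis precondition is not met (too few eyes, missing method, ...)."""
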