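"""Exception hierarchy.

All package errors derive from :class:`IsodendroError`.  Validation-type
failures (bad arguments, malformed files, impossible configurations) derive
from :class:`ValidationError` so the CLI can map them to exit code 2.
"""


class IsodendroError(Exception):
    """Base class for all package errors."""


class ValidationError(IsodendroError, ValueError):
    """Invalid arguments, configuration, or input files."""


class CoverageError(IsodendroError):
    """A required year or period is not covered by the data."""


class EmptySeriesError(IsodendroError):
    """An operation produced or received a series with no usable years."""


class EmptyChronologyError(EmptySeriesError):
    """No year reaches the replication gate."""


class DegenerateFitError(IsodendroError):
    """Regression impossible (e.g. zero proxy variance)."""


class InvalidSplitError(ValidationError):
    """Calibration and verification windows overlap or are malformed."""


class IntegrityError(ValidationError):
    """Duplicate or contradictory rows in an input table."""


class ParseError(ValidationError):
    """Malformed input file; message names the offending line."""
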