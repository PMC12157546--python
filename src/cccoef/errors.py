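"""Exception hierarchy.

All package errors derive from :class:`CccError` so callers can catch one
type at pipeline boundaries (the CLI does exactly that).
"""


class CccError(Exception):
    """Base class for all cccoef errors."""


class ParameterError(CccError, ValueError):
    """A configuration value or function argument is out of its valid domain."""


class DegenerateInputError(CccError, ValueError):
    """Input is structurally valid but carries no usable information
    (empty vector, all values missing, all coefficients undefined)."""


class ShapeError(CccError, ValueError):
    """Two objects that must share a sample/index space do not."""


class InsufficientDataError(CccError):
    """Too few pairwise-complete samples to compute the requested statistic."""


class ParseError(CccError, ValueError):
    """A text input file violates its format contract; message carries the
    line number and the offending token."""


class ConfigError(CccError, ValueError):
    """A run configuration is incomplete or inconsistent (e.g. an undeclared
    metadata column type)."""


class AlignmentError(CccError, ValueError):
    """Sample identifiers of two tables do not align; message lists offenders."""
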