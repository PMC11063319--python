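"""Exception hierarchy.

All input-contract violations raise :class:`ValidationError` (a ``ValueError``)
so callers can distinguish bad inputs (CLI exit code 1) from runtime faults
(exit code 2).
"""


class MethDriverError(Exception):
    """Base class for package errors."""


class ValidationError(MethDriverError, ValueError):
    """An input violates a documented precondition or invariant."""


class DimensionError(ValidationError):
    """Matrix shapes or index vocabularies do not line up."""


class EmptyResultError(ValidationError):
    """A filtering step removed every feature or sample."""
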