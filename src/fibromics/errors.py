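"""Exception hierarchy shared across the package.

Every user-facing failure is a :class:`FibromicsError` so callers (and the
CLI) can distinguish bad inputs from genuine bugs.
"""


class FibromicsError(Exception):
    """Base class for all package errors."""


class ParameterError(FibromicsError, ValueError):
    """An argument value violates its documented constraints."""


class DomainError(FibromicsError, ValueError):
    """Input values are outside the mathematical domain of an operation."""


class DesignError(FibromicsError, ValueError):
    """The experimental design is degenerate (missing groups, one level...)."""


class InsufficientDataError(FibromicsError, ValueError):
    """Too few observations to compute the requested quantity."""


class SchemaError(FibromicsError, ValueError):
    """A table does not match its expected schema."""
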