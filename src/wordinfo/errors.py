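"""Exception hierarchy shared across the package."""


class WordinfoError(Exception):
    """Base class for all package errors."""


class EmptySentenceError(WordinfoError):
    """Raised for empty or whitespace-only sentence input."""


class DegenerateSentenceError(WordinfoError):
    """Raised when a sentence has too few word tokens for a score to be defined."""


class EmptyInputError(WordinfoError):
    """Raised when an embedder is handed empty text."""


class ConfigurationError(WordinfoError):
    """Raised for unknown backends or invalid configuration values."""


class BackendError(WordinfoError):
    """Raised when an embedding backend fails mid-computation."""


class DegenerateVectorError(WordinfoError):
    """Raised for zero-norm vectors where cosine is undefined."""


class SchemaError(WordinfoError):
    """Raised when a tabular input lacks a required column."""


class ParseError(WordinfoError):
    """Raised for malformed values in tabular input, with row context."""


class UndefinedStatisticError(WordinfoError):
    """Raised when a correlation or z-score is undefined (too few pairs, zero variance)."""


class SeparationError(WordinfoError):
    """Raised when a logistic fit encounters (near-)perfect separation."""


class RankDeficiencyError(WordinfoError):
    """Raised when model terms are collinear; names the offending terms."""
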