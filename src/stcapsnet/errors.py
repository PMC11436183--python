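"""Exception hierarchy shared across the package.

All errors derive from :class:`ValueError` so callers that only care about
"bad input" can catch one base class.
"""


class STCapsError(ValueError):
    """Base class for all package-specific errors."""


class ConfigurationError(STCapsError):
    """A configuration object violates its invariants."""


class FormatError(STCapsError):
    """An on-disk container is missing fields or holds malformed arrays."""


class ShapeError(STCapsError):
    """Array geometry does not match what a layer or operation expects."""


class NumericError(STCapsError):
    """Non-finite values or numeric overflow where finite math is required."""


class DomainError(STCapsError):
    """A numeric argument lies outside its mathematically valid domain."""
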