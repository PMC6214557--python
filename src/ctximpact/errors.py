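"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: validation/format problems exit 2,
configuration problems exit 3, anything else exits 1.
"""


class CtximpactError(Exception):
    """Base class for all package errors."""


class FormatError(CtximpactError):
    """A file does not conform to the expected schema (e.g. missing column)."""


class ValidationError(CtximpactError):
    """A value violates a domain invariant (negative count, rate outside [0,1], ...)."""


class ConfigurationError(CtximpactError):
    """A run is not configured coherently (missing proxy, missing parameter, ...)."""


class InsufficientDataError(CtximpactError):
    """An operation was asked to summarize an empty collection."""
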