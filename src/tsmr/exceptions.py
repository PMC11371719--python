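"""Exception hierarchy shared across the package."""


class TsmrError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TsmrError):
    """A run configuration, column map, or parameter is invalid."""


class ValidationError(TsmrError):
    """Input data violates a hard invariant."""


class DuplicateSNPError(ValidationError):
    """The same snp_id appears more than once in a table."""


class NotEstimableError(TsmrError):
    """A method cannot be computed on the given instrument set
    (typically: too few instruments). Rendered as "/" in report tables."""


class DegenerateDesignError(TsmrError):
    """The regression design is degenerate (e.g. all exposure effects zero)."""
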