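"""Exception types shared across the package.

Exit-code mapping used by the CLI: DataError -> 1, UsageError /
ConfigurationError -> 2.
"""


class CricketsenError(Exception):
    """Base class for all package-specific errors."""


class DomainError(CricketsenError, ValueError):
    """A mathematical argument is outside its domain (negative age,
    non-positive parameter, probability outside (0, 1))."""


class DataError(CricketsenError, ValueError):
    """Input data violate the cohort / calling schemas (bad factor level,
    non-positive lifespan, duplicated id, empty treatment cell)."""


class ConfigurationError(CricketsenError, ValueError):
    """A model or experiment configuration is inconsistent (unknown term,
    parameter-vector length mismatch, composition outside tolerance)."""


class UsageError(CricketsenError, ValueError):
    """An operation was invoked in a way that makes no sense (non-nested
    models in a likelihood-ratio test, conflicting CLI flags)."""
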