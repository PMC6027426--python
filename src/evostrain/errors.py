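"""Exception types raised across the package."""


class EvostrainError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EvostrainError, ValueError):
    """A file could not be parsed in any supported dialect."""


class ConfigurationError(EvostrainError, ValueError):
    """A run configuration, model annotation, or target space is unusable."""


class InfeasibleModelError(EvostrainError, RuntimeError):
    """An operation requires a feasible model but the LP has no solution."""


class DomainError(EvostrainError, ValueError):
    """An argument violates a documented precondition."""
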