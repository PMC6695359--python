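"""Exception hierarchy shared across the package."""


class StgtSimError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(StgtSimError, ValueError):
    """A parameter, distribution or variant name is invalid."""


class InvalidActionError(StgtSimError, ValueError):
    """An action was requested in a state where it is not available."""


class StructuralError(StgtSimError, ValueError):
    """Inputs violate a structural precondition (misaligned subjects,
    wrong task variant, unbalanced design, missing columns...)."""
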