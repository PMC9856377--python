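"""Exception hierarchy for epibarrier."""


class EpibarrierError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EpibarrierError, ValueError):
    """Input violates a documented precondition or invariant."""


class StateError(EpibarrierError, RuntimeError):
    """Operation applied in an invalid state (e.g. double bath correction)."""


class DegenerateInputError(EpibarrierError, ValueError):
    """Input is formally valid but the requested quantity is not identifiable."""


class GeometryError(ValidationError):
    """Physically impossible crypt geometry."""


class UndefinedResultError(EpibarrierError):
    """The statistic is undefined for this input (distinct from zero)."""
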