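"""Exception hierarchy shared across the package."""


class VmatQaError(Exception):
    """Base class for all package errors."""


class ValidationError(VmatQaError, ValueError):
    """An object or argument violates a documented invariant."""


class FormatError(VmatQaError, ValueError):
    """A file cannot be parsed as the expected interchange format."""


class DeliveryFaultError(VmatQaError, RuntimeError):
    """A simulated machine interlock: a dynamic parameter left its tolerance."""


class UndefinedResultError(VmatQaError, ArithmeticError):
    """A requested statistic is undefined for the given input (e.g. empty mask)."""
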