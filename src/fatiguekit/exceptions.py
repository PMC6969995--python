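"""Exception hierarchy shared across the package."""


class FatigueKitError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(FatigueKitError, ValueError):
    """The input violates a precondition (wrong kind, too short, non-ascending...)."""


class UndefinedResultError(FatigueKitError, ArithmeticError):
    """The requested quantity is mathematically undefined for this input
    (e.g. median frequency of an all-zero spectrum, CV of a zero slope)."""


class DegenerateInputError(FatigueKitError, ValueError):
    """The input is formally valid but degenerate for the operation
    (e.g. Otsu thresholding of a constant image)."""
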