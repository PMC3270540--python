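"""Exception types shared across the package."""


class CooctexError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CooctexError, ValueError):
    """Raised when an input violates a documented precondition."""


class DegenerateInputError(CooctexError, ValueError):
    """Raised when an input is structurally valid but carries no information
    for the requested computation (e.g. an empty cooccurrence tensor).

    Callers assembling feature vectors catch this and record the feature as
    missing instead of aborting.
    """
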