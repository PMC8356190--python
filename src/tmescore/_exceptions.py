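"""Exception hierarchy shared across the package."""


class TmescoreError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(TmescoreError, ValueError):
    """Input data violates a documented invariant (duplicate ids, bad range ...)."""


class FormatError(TmescoreError, ValueError):
    """A file could not be parsed; the message names the offending line/cell."""


class CoverageError(ValidationError):
    """Too few signature (or housekeeping) genes present in the matrix."""


class ConvergenceError(TmescoreError, RuntimeError):
    """An iterative fit failed to converge (e.g. monotone Cox likelihood)."""
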