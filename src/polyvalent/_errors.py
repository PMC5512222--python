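"""Exception hierarchy shared across the package."""


class PolyvalentError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PolyvalentError, ValueError):
    """Input data violates a documented invariant."""


class ParseError(ValidationError):
    """A file or string does not match its declared dialect."""


class UsageError(PolyvalentError, ValueError):
    """An operation was called with arguments outside its contract."""


class SizeError(UsageError):
    """Not enough data points for the requested computation."""


class DegenerateError(UsageError):
    """The input admits no meaningful fit (e.g. all values equal, no edges)."""


class ConvergenceError(PolyvalentError, RuntimeError):
    """An iterative procedure failed to converge within its budget."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class ConfigError(ValidationError):
    """A generator or run configuration is internally inconsistent."""
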