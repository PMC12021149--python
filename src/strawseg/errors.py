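"""Exception hierarchy shared across the package."""


class StrawsegError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(StrawsegError, ValueError):
    """A configuration value violates its contract (e.g. min > max)."""


class GenerationError(StrawsegError, RuntimeError):
    """Procedural generation could not satisfy an invariant within its retry budget."""


class DataError(StrawsegError, ValueError):
    """A dataset-level contract is violated (empty manifest, shape mismatch, ...)."""


class FormatError(StrawsegError, ValueError):
    """An on-disk file does not match the expected format (e.g. stray mask values)."""


class NumericError(StrawsegError, ArithmeticError):
    """A numeric invariant failed (NaN/Inf in a network output)."""
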