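"""Exception hierarchy shared across the package."""


class StreampopError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(StreampopError, ValueError):
    """A parameter violates its contract (sign, range, divisibility...)."""


class ResolutionError(StreampopError, ValueError):
    """The grid is too coarse to resolve a kernel or transport step."""


class DomainError(StreampopError, ValueError):
    """A field leaves the admissible range of a nonlinearity."""


class UnsupportedProfileError(StreampopError, ValueError):
    """A habitat profile does not expose the tail behaviour an operation needs."""


class ConfigError(StreampopError, ValueError):
    """A run configuration file is malformed."""


class DivergenceError(StreampopError, RuntimeError):
    """A trajectory blew past the divergence guard."""


class MemoryGuardError(StreampopError, MemoryError):
    """A dense operator would be too large; use the matrix-free path."""
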