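"""Exception hierarchy shared across the package."""


class InversePairError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(InversePairError):
    """Invalid user-supplied configuration (unknown gene ids, bad keys, ...)."""


class GenerationError(InversePairError):
    """Synthetic-data generation could not satisfy its constraints."""


class QCError(InversePairError):
    """Quality-control step produced an unusable result (e.g. no cells left)."""


class ValidationError(InversePairError):
    """Input data violates an operation's preconditions."""


class ZeroVarianceError(ValidationError):
    """A correlation was requested on a constant vector."""
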