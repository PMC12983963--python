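"""Exception hierarchy shared across the package."""


class ColdStressError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ColdStressError):
    """A configuration document is incomplete or self-contradictory."""


class ValidationError(ColdStressError, ValueError):
    """An input value violates a documented invariant."""


class ConsistencyError(ColdStressError):
    """A judgment matrix failed the consistency-ratio check."""


class DomainError(ColdStressError, ValueError):
    """A numeric value lies outside its declared domain."""


class SchemaError(ColdStressError):
    """A record or table is missing required fields or has bad shape."""


class InsufficientDataError(ColdStressError):
    """Too few observations to compute the requested statistic."""


class DegenerateInputError(ColdStressError):
    """Input is formally valid but the operation is undefined on it."""
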