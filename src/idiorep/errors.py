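"""Exception hierarchy shared across the package."""


class IdiorepError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(IdiorepError):
    """A required column or field is missing from an input table."""


class ValidationError(IdiorepError):
    """An input value violates a documented contract."""


class ConfigurationError(IdiorepError):
    """A configuration object is internally inconsistent."""


class MisassignmentError(IdiorepError):
    """A sequence does not plausibly derive from the germline it was assigned to."""


class GenerationError(IdiorepError):
    """The synthetic generator cannot satisfy the requested constraint."""


class EstimateError(IdiorepError):
    """A statistic is undefined for the given input (e.g. empty abundance vector)."""
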