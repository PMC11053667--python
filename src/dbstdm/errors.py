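"""Exception hierarchy for the DBS-TDM pipeline.

Every error raised deliberately by this package derives from :class:`DbsTdmError`,
so callers can catch pipeline failures without masking programming errors.
"""


class DbsTdmError(Exception):
    """Base class for all errors raised by dbstdm."""


class SchemaError(DbsTdmError):
    """An input table is missing a required column or has an unusable layout."""


class DataValidationError(DbsTdmError):
    """A record violates a domain invariant (negative concentration, Hct out of range...)."""


class DomainError(DbsTdmError):
    """A numeric argument is outside the mathematical domain of an operation."""


class InsufficientDataError(DbsTdmError):
    """Too few observations for the requested statistic."""


class DesignError(DbsTdmError):
    """The experimental design does not meet the guideline minimum (levels, volumes...)."""


class EstimationError(DbsTdmError):
    """An iterative estimator failed to converge."""


class ConfigError(DbsTdmError):
    """A run configuration contains unknown keys or inconsistent values."""
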