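"""Exception hierarchy for the dietfootprint pipeline.

Every error raised by this package derives from :class:`DietFootprintError`,
so callers can catch pipeline failures without masking programming errors.
"""


class DietFootprintError(Exception):
    """Base class for all errors raised by dietfootprint."""


class SchemaError(DietFootprintError):
    """A tabular input is missing a required column or has the wrong layout."""


class ValidationError(DietFootprintError):
    """A value violates an invariant (negative quantity, duplicate key, ...)."""


class ConfigurationError(DietFootprintError):
    """A configuration constant or option is invalid."""


class TaxonomyError(DietFootprintError):
    """A food group is unknown to, or inconsistent with, the taxonomy."""


class MappingError(DietFootprintError):
    """An item cannot be mapped to emission-table foods."""


class StageError(DietFootprintError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
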