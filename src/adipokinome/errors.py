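"""Exception hierarchy for the adipokinome pipeline.

Every stage raises a subclass of :class:`AdipokinomeError`, so callers can
catch pipeline failures without masking programming errors.
"""


class AdipokinomeError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(AdipokinomeError):
    """An input table is missing required columns or has the wrong types."""


class IntegrityError(AdipokinomeError):
    """Duplicate keys or internally inconsistent records in an input."""


class ValidationError(AdipokinomeError):
    """A field value is outside its allowed domain (e.g. rank not in 0..12)."""


class SizingError(AdipokinomeError):
    """Requested sizes are infeasible (e.g. more substrates than peptides)."""


class InputError(AdipokinomeError):
    """An input object is empty or otherwise unusable."""


class DegenerateDesignError(AdipokinomeError):
    """Regression design with no spread in the predictor."""


class InsufficientDataError(AdipokinomeError):
    """Too few observations for the requested fit."""


class PairingError(AdipokinomeError):
    """Case and control tables share no peptides/chips to compare."""


class ReplicationError(AdipokinomeError):
    """An operation requiring technical replicates got a single chip."""


class EmptySelectionError(AdipokinomeError):
    """A scoping/filter step left nothing to operate on."""


class StageError(AdipokinomeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
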