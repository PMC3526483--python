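"""Typed exceptions raised across the package."""


class ModmindError(Exception):
    """Base class for all package errors."""


class DesignError(ModmindError):
    """Invalid or inconsistent study design."""


class DatasetError(ModmindError):
    """Invalid observation data (construction-time)."""


class DatasetParseError(DatasetError):
    """Malformed observation file; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class ModelSpecError(ModmindError):
    """Model specification outside the supported grid or inconsistent with the design."""


class InactiveEffectError(ModelSpecError):
    """An operation referenced a random effect the model does not include."""


class AssessmentError(ModmindError):
    """Discrepancy / assessment request incompatible with the fitted model."""


class PipelineConfigError(ModmindError):
    """Invalid pipeline configuration."""
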