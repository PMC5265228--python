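"""Exception hierarchy for the datspect_normdb package."""


class DatspectError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(DatspectError, ValueError):
    """Invalid user input (parameters, specs, configs)."""


class GeometryError(ValidationError):
    """Structures do not fit the voxel grid or violate geometric invariants."""


class QuantificationError(DatspectError):
    """SBR quantification cannot proceed (e.g. non-positive reference)."""


class CalibrationError(DatspectError):
    """Calibration fitting or application failed."""


class ModelError(DatspectError):
    """Normal-range model fitting or evaluation failed."""


class EvaluationError(DatspectError):
    """Diagnostic-performance statistic is undefined for the given input."""


class ConfigError(ValidationError):
    """Malformed study configuration or serialised artefact."""
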