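"""Exception hierarchy shared across the pipeline."""


class TriageShiftError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(TriageShiftError):
    """Invalid profile, unit declaration, or artifact configuration."""


class SizingError(TriageShiftError):
    """Insufficient rows: empty cohort, pool too small, k > |source|."""


class DataError(TriageShiftError):
    """Data content violates an operation's precondition (e.g. all-missing feature)."""


class SchemaError(TriageShiftError):
    """Required column absent or misaligned inputs."""


class TrainingError(TriageShiftError):
    """Classifier training cannot proceed (e.g. single-class labels)."""


class CalibrationError(TriageShiftError):
    """Threshold calibration cannot proceed (e.g. no positive labels)."""


class MetricError(TriageShiftError):
    """Metric undefined on the given input (e.g. single-class AUROC)."""


class ProtocolError(TriageShiftError):
    """Experiment-protocol violation (e.g. adaptation/evaluation row overlap)."""


class UnsupportedOperationError(TriageShiftError):
    """Operation not applicable to this model kind (e.g. fine-tuning trees)."""
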