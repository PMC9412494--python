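"""Exception and warning types shared across the pipeline."""


class KinegaitError(Exception):
    """Base class for all kinegait errors."""


class TrialParseError(KinegaitError):
    """The trial file is not valid JSON."""


class SchemaError(KinegaitError):
    """The trial file parses but violates the trial schema."""


class DataError(KinegaitError):
    """Schema-valid content violating a data invariant (e.g. timestamps)."""


class UnknownJointError(KinegaitError, KeyError):
    """A joint name that is not part of the 32-joint skeleton."""


class InsufficientDataError(KinegaitError):
    """Too few samples for the requested operation."""


class EmptyWindowError(KinegaitError):
    """The pelvis never enters the gait analysis path."""


class InsufficientProgressError(KinegaitError):
    """Too little forward travel to define a reference walking line."""


class NoEventsError(KinegaitError):
    """No qualifying gait events found in the window."""


class UndefinedAsymmetryError(KinegaitError):
    """Both sides of an asymmetry pair are zero."""


class UndefinedCorrelationError(KinegaitError):
    """A synchrony series has zero variance."""


class ConfigError(KinegaitError):
    """Invalid simulator or cohort configuration."""


class PipelineStageError(KinegaitError):
    """A stage of per-trial analysis failed.

    Carries the stage name and trial identifier so batch runs can report
    which trial broke and where.
    """

    def __init__(self, stage: str, trial: str, cause: Exception):
        self.stage = stage
        self.trial = trial
        self.cause = cause
        super().__init__(f"stage '{stage}' failed for trial '{trial}': {cause}")


class TruncatedWindowWarning(UserWarning):
    """The pelvis enters the GAP but the trial ends before it leaves."""


class SegmentationWarning(UserWarning):
    """Detected heel strikes of the two sides do not alternate."""


class DegenerateGeometryWarning(UserWarning):
    """Degenerate geometry (collinear hull points, near-zero segments)."""
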