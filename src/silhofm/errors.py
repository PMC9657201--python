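"""Exception hierarchy for the silhouette body-composition pipeline."""


class SilhofmError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(SilhofmError, ValueError):
    """An argument violates a documented precondition."""


class RenderingBoundsError(SilhofmError):
    """The requested body does not fit in the image at the given scale."""


class InvalidInputError(SilhofmError, ValueError):
    """An input image or vector is unusable (empty, mismatched, degenerate)."""


class NoSubjectError(InvalidInputError):
    """Thresholding produced an empty foreground."""


class FramingError(InvalidInputError):
    """The silhouette touches the left, right or top image border."""


class DegenerateInputError(InvalidInputError):
    """Silhouette too small/short for landmark analysis."""


class LandmarkFailureError(SilhofmError):
    """Landmark detection produced an inconsistent or empty result."""


class FrameOverflowError(SilhofmError):
    """The silhouette is wider than the virtual frame at the given fraction."""


class DegenerateFrameError(SilhofmError):
    """The virtual frame contains no background pixels."""


class CollinearityError(SilhofmError):
    """Rank-deficient design matrix in model training."""

    def __init__(self, message, features=()):
        super().__init__(message)
        self.features = tuple(features)


class SampleSizeError(SilhofmError):
    """Too few training records for the requested model."""


class ContractError(SilhofmError):
    """Model/feature contract violation (gender or feature-name mismatch)."""


class ModelFileError(SilhofmError, ValueError):
    """Malformed or unsupported model file."""


class PipelineStageError(SilhofmError):
    """A pipeline stage failed; carries the stage name and subject id."""

    def __init__(self, stage, subject_id, cause):
        super().__init__(f"stage '{stage}' failed for subject '{subject_id}': {cause}")
        self.stage = stage
        self.subject_id = subject_id
        self.cause = cause
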