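"""Exception hierarchy for the trichome-counting pipeline."""


class TrichocountError(Exception):
    """Base class for all package errors."""


class FormatError(TrichocountError):
    """Input image or file does not have the expected format."""


class DegenerateSegmentationError(TrichocountError):
    """Segmentation produced an all-foreground or all-background mask."""


class EmptyMaskError(TrichocountError):
    """An operation that requires foreground pixels received an empty mask."""


class AnnotationError(TrichocountError):
    """An annotation curve could not be loaded or extracted."""


class SceneError(TrichocountError):
    """A synthetic scene specification is infeasible."""


class EvaluationError(TrichocountError):
    """Evaluation inputs are unusable (length mismatch, constant reference)."""


class StageError(TrichocountError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
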