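"""Exception hierarchy for the pdmotion pipeline.

Every stage raises a subclass of :class:`PdMotionError` so callers can
distinguish pipeline failures from programming errors.
"""


class PdMotionError(Exception):
    """Base class for all pdmotion errors."""


class SchemaError(PdMotionError):
    """A recording file violates the XML/CSV schema; message names the field."""


class ParameterError(PdMotionError, ValueError):
    """An argument is outside its valid domain (bad cutoff, empty series, ...)."""


class TaskMismatchError(PdMotionError):
    """A recording of the wrong motor task was passed to an extractor."""


class InsufficientEventsError(PdMotionError):
    """Too few stride/step events were detected to compute gait features."""


class DegenerateLabelsError(PdMotionError):
    """Classification or regression target has a single distinct value."""


class PipelineStageError(PdMotionError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
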