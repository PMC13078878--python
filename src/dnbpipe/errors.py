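"""Exception hierarchy shared across the pipeline."""


class DnbPipeError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(DnbPipeError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(DnbPipeError, ValueError):
    """An input file violates its expected format."""


class EmptyResultError(DnbPipeError, ValueError):
    """An operation produced no usable output (e.g. all genes filtered)."""


class EmptyCandidatesError(EmptyResultError):
    """No candidate module satisfied the size bounds at any tree cut."""


class PipelineStageError(DnbPipeError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
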