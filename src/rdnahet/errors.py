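"""Exception hierarchy."""


class RdnahetError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(RdnahetError, ValueError):
    """A parameter violates its documented precondition."""


class InvalidInputError(RdnahetError, ValueError):
    """An input object is malformed or insufficient for the operation."""


class FastaParseError(RdnahetError, ValueError):
    """Malformed FASTA input; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class PipelineStageError(RdnahetError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
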