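"""Exception hierarchy shared across the package."""


class CutevoError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CutevoError):
    """A file or string does not conform to its expected format."""


class ValidationError(CutevoError):
    """Input parsed correctly but violates a documented invariant."""


class NewickParseError(FormatError):
    """Malformed newick / SIMMAP text; carries position info when known."""


class UltrametricError(ValidationError):
    """Root-to-tip path sums disagree beyond tolerance."""

    def __init__(self, message: str, max_deviation: float | None = None):
        super().__init__(message)
        self.max_deviation = max_deviation


class PipelineStageError(CutevoError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
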