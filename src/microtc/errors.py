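"""Exception hierarchy shared across the toolkit."""


class MicrotcError(Exception):
    """Base class for all toolkit errors."""


class MatrixFormatError(MicrotcError, ValueError):
    """Raised when an expression-matrix table violates its format contract."""


class DesignError(MicrotcError, ValueError):
    """Raised when an experiment-design document is inconsistent."""


class UnreplicatedError(DesignError):
    """A sample set has fewer than two replicate chips.

    Unreplicated sample sets are inadmissible: every downstream statistic
    (standard deviation, %CV, t-test) needs at least two replicates.
    """


class SoftFormatError(MicrotcError, ValueError):
    """Raised when a SOFT series-matrix file is malformed."""


class AnnotationError(MicrotcError, ValueError):
    """Raised on invalid probe or transcript input."""


class PipelineError(MicrotcError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
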