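"""Exception hierarchy shared across the package."""


class CcfriskError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CcfriskError, ValueError):
    """A file does not follow the expected tabular dialect (e.g. missing column)."""


class ValidationError(CcfriskError, ValueError):
    """Parsed content violates a domain invariant (e.g. alt reads > depth)."""


class ConvergenceError(CcfriskError, RuntimeError):
    """An iterative fit failed to converge within its iteration budget."""


class PipelineError(CcfriskError, RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
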