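"""Exception hierarchy shared across the package."""


class PsimapError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PsimapError):
    """A file could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += f"{path}"
        if line is not None:
            prefix += f", line {line}"
        super().__init__(f"{prefix}: {message}" if prefix else message)


class ValidationError(PsimapError):
    """Input violated a documented precondition or invariant."""


class PipelineError(PsimapError):
    """A pipeline stage failed; names the stage so callers can locate it."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
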