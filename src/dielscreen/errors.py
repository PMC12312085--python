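"""Exception hierarchy.

``ValidationError`` signals malformed or contract-violating input (CLI exit
code 2); ``StageError`` signals a failure inside a pipeline stage (exit
code 3).
"""


class DielscreenError(Exception):
    """Base class for all package errors."""


class ValidationError(DielscreenError, ValueError):
    """Input data or configuration violates a documented contract."""


class StageError(DielscreenError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
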