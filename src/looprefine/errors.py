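"""Exception hierarchy shared by all looprefine modules."""


class LooprefineError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(LooprefineError):
    """Malformed input: files, tables, selectors, configuration."""


class StructureError(LooprefineError):
    """Inconsistent or incomplete molecular structure."""


class ConvergenceError(LooprefineError):
    """An iterative solver failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ClashError(LooprefineError):
    """Generated geometry contains atom-atom clashes."""
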