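"""Exception hierarchy for slsorb."""


class SlsorbError(Exception):
    """Base class for all package-specific errors."""


class DomainError(SlsorbError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class NoDensityRootError(SlsorbError, ArithmeticError):
    """The equation of state has no density root at the requested state."""

    def __init__(self, message, *, T=None, p=None, Ttilde=None, ptilde=None):
        super().__init__(message)
        self.T = T
        self.p = p
        self.Ttilde = Ttilde
        self.ptilde = ptilde


class ConvergenceError(SlsorbError, ArithmeticError):
    """An iterative solver failed to reach its tolerance."""

    def __init__(self, message, *, last_iterate=None, residual=None):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.residual = residual


class ParseError(SlsorbError, ValueError):
    """An input file could not be parsed."""


class PipelineStageError(SlsorbError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, message):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
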