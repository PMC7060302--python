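"""Exception hierarchy for the toolkit."""


class MibgDoseError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(MibgDoseError):
    """Input data violates a precondition (user error)."""


class FitError(MibgDoseError):
    """A model fit failed to converge or is inconsistent."""

    def __init__(self, message, initial_values=None, trace=None):
        super().__init__(message)
        self.initial_values = initial_values
        self.trace = trace


class StageError(MibgDoseError):
    """A pipeline stage failed; carries the stage name for CLI reporting."""

    def __init__(self, stage, cause):
        super().__init__(f"stage '{stage}': {cause}")
        self.stage = stage
        self.cause = cause
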