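"""Exception hierarchy shared across the package."""


class CTOTError(Exception):
    """Base class for all package-specific errors."""


class DataValidationError(CTOTError, ValueError):
    """Raised when an input table or frame violates the data contract."""


class ConvergenceError(CTOTError, RuntimeError):
    """Raised when an iterative fit fails to converge (e.g. monotone
    partial likelihood); never returns a silent estimate."""


class AnalysisNotPossible(CTOTError, RuntimeError):
    """The CNA outcome: the requested analysis cannot be carried out on
    the available data (e.g. a group has <2 complete observations)."""
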