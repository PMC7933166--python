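"""Exception hierarchy shared across the pipeline stages."""


class PainsignalError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PainsignalError):
    """A configuration value is missing, non-finite, or out of range."""


class WindowUnavailableError(PainsignalError):
    """The evaluation time is too early for a full one-hour window."""


class BaselineUnavailableError(PainsignalError):
    """Fewer than 60 baseline windows satisfy the 90% presence rule."""


class DegenerateBaselineError(PainsignalError):
    """Baseline fluctuation range is (numerically) zero; leveling undefined."""


class RassUnavailableError(PainsignalError):
    """No RASS assessment within the 3-hour lookback of an evaluation time."""


class ResamplingError(PainsignalError):
    """Oversampling cannot proceed (single class, lone minority point, ...)."""


class StratificationError(PainsignalError):
    """A cross-validation fold would contain a single class."""


class RocUndefinedError(PainsignalError):
    """ROC analysis requires both positive and negative labels."""


class StageError(PainsignalError):
    """A pipeline stage failed; carries the stage name and a remediation hint."""

    def __init__(self, stage: str, message: str, hint: str | None = None):
        self.stage = stage
        self.hint = hint
        text = f"stage '{stage}' failed: {message}"
        if hint:
            text += f" (hint: {hint})"
        super().__init__(text)
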