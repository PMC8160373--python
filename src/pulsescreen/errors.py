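"""Exception types shared across the pipeline stages."""


class PulseScreenError(Exception):
    """Base class for all pipeline errors."""


class SignalQualityError(PulseScreenError):
    """Signal too noisy / implausible for beat detection."""


class SessionQualityError(PulseScreenError):
    """Session-level rejection (too many artifacts or missing frames)."""


class InsufficientDataError(PulseScreenError):
    """Not enough accepted intervals in a protocol period."""


class UndefinedDeltaError(PulseScreenError):
    """Percent-change delta with a zero denominator."""


class SeparationError(PulseScreenError):
    """Complete separation during logistic-regression fitting."""


class FlatSignalError(SignalQualityError):
    """ECG channel carries no signal."""


class DegenerateRoiError(PulseScreenError):
    """Zero-area region of interest."""


class StageError(PulseScreenError):
    """Wraps a failure with the pipeline stage it occurred in."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
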