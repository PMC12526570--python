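"""Exception types shared across the package."""


class PPGRhythmError(Exception):
    """Base class for package errors."""


class InvalidParameterError(PPGRhythmError, ValueError):
    """A configuration or argument value violates its contract."""


class DegenerateSignalError(PPGRhythmError, ValueError):
    """The input signal is degenerate for the requested operation (e.g. constant)."""


class SignalTooShortError(PPGRhythmError, ValueError):
    """The input signal is too short for the requested operation."""


class ShapeError(PPGRhythmError, ValueError):
    """Array shapes are inconsistent with the operation's contract."""


class LeakageError(PPGRhythmError, RuntimeError):
    """Record-level leakage detected between data splits."""
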