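"""Exception hierarchy."""


class FiltrackError(Exception):
    """Base class for all filtrack errors."""


class InvalidCurveError(FiltrackError):
    """A curve does not satisfy the preconditions of an operation."""


class InvalidTipError(FiltrackError):
    """A tip has a degenerate (zero-length) tangent."""


class InvalidEdgeError(FiltrackError):
    """A correspondence edge violates the forward-in-time constraint."""


class InconsistentPairingError(FiltrackError):
    """A tip participates in more than one splice pairing."""


class InsufficientDataError(FiltrackError):
    """Not enough samples to perform a fit or estimate."""


class InvalidParameterError(FiltrackError):
    """A parameter value is outside its valid range."""


class IntegrityError(FiltrackError):
    """A cross-reference (track -> curve, tip -> curve) is dangling."""


class FormatError(FiltrackError):
    """A file has an unexpected structure or mixed dimensionality."""


class ParseError(FormatError):
    """A text file failed to parse; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
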