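"""Exception hierarchy shared across the pipeline stages."""


class RPPGStressError(Exception):
    """Base class for all package errors."""


class InputError(RPPGStressError, ValueError):
    """Malformed or out-of-contract input (shapes, ranges, lengths)."""


class DegenerateSignalError(RPPGStressError, ValueError):
    """A signal whose statistics make the operation undefined
    (zero-mean channel, zero-variance chrominance)."""


class TooShortSeriesError(RPPGStressError, ValueError):
    """Heart-rate series with fewer than 3 usable intervals."""


class ValidationError(RPPGStressError, ValueError):
    """Dataset-level contract violation (single-class data, class
    counts below the fold count, ...)."""


class VideoIOError(RPPGStressError, IOError):
    """Undecodable or unreadable video input."""


class ArffParseError(RPPGStressError, ValueError):
    """Malformed ARFF content; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line
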