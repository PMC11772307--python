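"""Exception hierarchy for turtlehr.

All validation problems derive from :class:`ValidationError` (a ``ValueError``)
so callers can catch one type; format/parsing problems on channel files get
their own subclasses carrying file context.
"""


class TurtleHRError(Exception):
    """Base class for all turtlehr errors."""


class ValidationError(TurtleHRError, ValueError):
    """An input violates a documented invariant (bad rate, band, threshold...)."""


class ChannelFormatError(TurtleHRError, ValueError):
    """A channel file's header block is malformed (missing/duplicate keys)."""


class ChannelParseError(TurtleHRError, ValueError):
    """A sample line in a channel file is not numeric.

    Carries ``line_number`` (1-based, counting header lines).
    """

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number


class IncompleteDeploymentError(TurtleHRError, ValueError):
    """A deployment is missing a required channel (``ecg`` or ``accel_long``)."""


class GenerationError(TurtleHRError, ValueError):
    """Synthetic-data parameters are mutually implausible (e.g. beat template
    wider than the shortest RR interval they would produce)."""


class TooShortError(TurtleHRError, ValueError):
    """A record is too short for the requested operation (filter warm-up,
    quality windowing on an empty record...)."""


class StageError(TurtleHRError, RuntimeError):
    """A pipeline stage failed; ``stage`` names the failing step."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original
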