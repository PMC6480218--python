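"""Exception hierarchy for tugseg.

All failures raised by the library derive from :class:`TugsegError` so callers
can catch one base class; the CLI maps subclasses to exit codes.
"""


class TugsegError(Exception):
    """Base class for all tugseg errors."""


class SchemaError(TugsegError):
    """Input file does not match the expected column schema."""


class DataError(TugsegError):
    """Input data violates a precondition (non-monotone time, too short, ...)."""


class ConfigError(TugsegError):
    """Invalid algorithm configuration."""


class DetectionError(TugsegError):
    """A required event (posture peak, turn extremum) could not be found.

    ``stage`` names the detector that failed.
    """

    def __init__(self, message: str, stage: str = ""):
        super().__init__(message)
        self.stage = stage


class ConsistencyError(TugsegError):
    """Detected events violate the required sub-task ordering."""
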