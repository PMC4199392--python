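"""Exception types shared across the package."""


class BeatgainError(Exception):
    """Base class for package-specific errors."""


class SchemaError(BeatgainError, ValueError):
    """A table is missing required columns or has malformed ones."""


class IntegrityError(BeatgainError, ValueError):
    """Table contents violate a structural invariant (e.g. unordered taps)."""


class StaircaseError(BeatgainError, RuntimeError):
    """The adaptive staircase failed to converge; carries the level trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class InsufficientDataError(BeatgainError, ValueError):
    """Too few observations for the requested estimate."""


class DegenerateSampleError(BeatgainError, ValueError):
    """A sample whose variance is zero where a variance is required."""
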