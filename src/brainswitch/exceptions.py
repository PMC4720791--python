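"""Exception hierarchy shared across the pipeline."""


class BrainSwitchError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(BrainSwitchError, ValueError):
    """A parameter violates its documented precondition."""


class MissingChannelError(BrainSwitchError, KeyError):
    """A required channel label is absent from a recording."""


class BoundaryError(BrainSwitchError, ValueError):
    """An epoch or window would extend past the edge of the recording."""


class InsufficientDataError(BrainSwitchError, ValueError):
    """Too few trials/runs/samples to run the requested analysis."""


class DegenerateDataError(BrainSwitchError, ValueError):
    """Input data are numerically degenerate (e.g. zero variance)."""


class DegenerateReferenceError(BrainSwitchError, ValueError):
    """The reference-interval power is zero for some frequency."""
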