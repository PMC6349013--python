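"""Exception hierarchy for the bindscape pipeline.

Every stage raises a subclass of :class:`BindscapeError` so callers (and the
CLI) can distinguish user-input problems from genuine bugs.
"""


class BindscapeError(Exception):
    """Base class for all bindscape errors."""


class FrameDegeneracyError(BindscapeError):
    """Anchor geometry cannot define a right-handed frame (zero-length or
    collinear anchor vectors)."""


class ProjectionUndefinedError(BindscapeError):
    """A point coincides with the frame origin; its direction, and hence its
    geographic position, is undefined."""


class SelectorError(BindscapeError):
    """An atom selector resolved to zero or more than one atom."""


class CorrespondenceError(BindscapeError):
    """Two coordinate sets that must be in one-to-one correspondence have
    different lengths."""


class InputError(BindscapeError):
    """A value or collection violates an operation's preconditions
    (empty atom set, too-short series, nonpositive Kd, ...)."""


class FitError(BindscapeError):
    """A surface fit cannot be performed (degenerate node set)."""


class PathwayUnavailableError(BindscapeError):
    """Pathway extraction was requested for a trajectory that never reaches a
    stable bound state."""


class DependencyError(BindscapeError):
    """A pipeline stage was invoked before the stage it depends on.

    Carries the name of the missing upstream stage.
    """

    def __init__(self, stage: str, message: str | None = None):
        self.stage = stage
        super().__init__(message or f"missing upstream stage: {stage}")


class ConfigError(BindscapeError):
    """A run configuration failed validation; lists the offending keys."""

    def __init__(self, keys: list[str], message: str | None = None):
        self.keys = list(keys)
        super().__init__(message or f"invalid config keys: {', '.join(self.keys)}")
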