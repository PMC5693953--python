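"""Exception hierarchy shared across the package."""


class ClimepiError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(ClimepiError, ValueError):
    """A parameter violates its documented domain (e.g. |phi| >= 1)."""


class InsufficientDataError(ClimepiError, ValueError):
    """Too few points for the requested fit or window."""


class DegenerateSeriesError(ClimepiError, ValueError):
    """A series is constant (or otherwise carries no usable variance)."""


class AlignmentError(ClimepiError, ValueError):
    """Two series or a series and a field do not share the same years."""


class DomainError(ClimepiError, ValueError):
    """A spatial subsetting box does not intersect the grid, or a selection is empty."""


class IncompleteReportError(ClimepiError, ValueError):
    """A study report is missing a stage required by the summary."""


class StageError(ClimepiError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: BaseException):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original!r}")
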