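"""Exception hierarchy shared across the pipeline stages."""


class MitoscopeError(Exception):
    """Base class for all package errors."""


class ValidationError(MitoscopeError, ValueError):
    """A configuration or argument violates a documented precondition."""


class DegenerateStatisticsError(MitoscopeError, ValueError):
    """A frame has zero variance on at least one color channel."""


class PlacementError(MitoscopeError, RuntimeError):
    """Non-overlapping nucleus placement failed within the retry budget."""


class DivergenceError(MitoscopeError, RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")
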