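"""Exception types shared across the pipeline."""


class SockGaitError(Exception):
    """Base class for all package errors."""


class ConfigError(SockGaitError):
    """Invalid configuration value (rates out of range, bad sampling rates, ...)."""


class DegenerateInputError(SockGaitError):
    """Input too short or otherwise degenerate for the requested operation."""


class AlignmentUndefinedError(SockGaitError):
    """Cross-correlation alignment is undefined (e.g. a constant channel)."""


class EmptyTrialError(SockGaitError):
    """All gait cycles were flagged; nothing remains to analyse."""


class RankDeficientError(SockGaitError):
    """The regression design matrix is rank deficient."""

    def __init__(self, channels):
        self.channels = list(channels)
        super().__init__(
            "design matrix is rank deficient; collinear channels: "
            + ", ".join(map(str, self.channels))
        )


class TrainingDivergedError(SockGaitError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch):
        self.epoch = epoch
        super().__init__(f"non-finite loss at epoch {epoch}")


class ModelShapeError(SockGaitError):
    """A layer cannot be applied to the incoming tensor shape."""
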