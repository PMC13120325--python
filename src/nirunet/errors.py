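"""Exception types shared across the package."""


class NirUnetError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(NirUnetError, ValueError):
    """A configuration value is invalid or inconsistent."""


class DomainError(NirUnetError, ValueError):
    """An argument is outside the operation's domain (shape, range, index)."""


class FormatError(NirUnetError, ValueError):
    """A file does not follow the expected on-disk format."""


class EvaluationError(NirUnetError, RuntimeError):
    """A reconstruction method misbehaved during batch evaluation."""


class TrainingDivergenceError(NirUnetError, RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")
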