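"""Exception hierarchy shared by all pathospeech modules."""


class PathoSpeechError(Exception):
    """Base class for all package errors."""


class InputError(PathoSpeechError):
    """Unreadable or malformed external input (files, tables)."""


class ValidationError(PathoSpeechError):
    """A precondition on in-memory data was violated."""


class SegmentationError(PathoSpeechError):
    """Passage segmentation could not satisfy the break specification."""


class ConfigurationError(PathoSpeechError):
    """Inconsistent model weights or architecture settings."""


class TrainingDivergenceError(PathoSpeechError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")


class ConflictError(PathoSpeechError):
    """An insert collided with an existing record."""


class ReferentialError(PathoSpeechError):
    """An operation referenced a patient that does not exist."""


class NotFoundError(PathoSpeechError):
    """An operation referenced an entry that does not exist."""
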