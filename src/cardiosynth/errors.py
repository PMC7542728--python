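"""Named exception types used across the package."""


class CardioSynthError(Exception):
    """Base class for all package errors."""


class InvalidViewError(CardioSynthError):
    """Unknown imaging view (must be 'SAX' or 'LAX')."""


class ResolutionError(CardioSynthError):
    """Resolution is not a supported power of two, or out of range."""


class ShapeMismatchError(CardioSynthError):
    """Two arrays that must share a shape do not."""


class StageError(CardioSynthError):
    """Growth-stage index out of range."""


class EmptyDatasetError(CardioSynthError):
    """A training/reference set is empty where at least one item is required."""


class DegenerateInputError(CardioSynthError):
    """Statistically degenerate input (e.g. all paired differences zero)."""


class FrameReadError(CardioSynthError):
    """A frame file could not be read under the stated contract."""


class OutputPathError(CardioSynthError):
    """An output location cannot be created or written."""


class ConfigError(CardioSynthError):
    """Invalid or inconsistent configuration."""


class TrainingDivergedError(CardioSynthError):
    """A training loop produced a non-finite loss."""
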