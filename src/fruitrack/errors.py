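"""Exception hierarchy shared across fruitrack modules."""


class FruitrackError(Exception):
    """Base class for all fruitrack errors."""


class ValidationError(FruitrackError, ValueError):
    """Input violates a documented precondition (bad box, empty mask, ...)."""


class ParseError(FruitrackError, ValueError):
    """A text record could not be parsed; message names the offending line."""


class ConfigurationError(FruitrackError, ValueError):
    """Unknown option value (detector backend, augmentation op, ...)."""


class SequencingError(FruitrackError, RuntimeError):
    """Frames fed to the tracker out of order."""
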