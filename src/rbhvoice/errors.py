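"""Exception hierarchy shared across the package."""


class RbhVoiceError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RbhVoiceError):
    """A file could not be parsed under the declared format."""


class ValidationError(RbhVoiceError):
    """Input data violates a documented invariant."""


class ConfigError(RbhVoiceError):
    """A configuration value is inconsistent with the input."""


class UndefinedValueError(RbhVoiceError):
    """A statistic is undefined for the given input (e.g. too few cycles)."""


class EmptyTrackError(RbhVoiceError):
    """The signal is shorter than a single analysis frame."""
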