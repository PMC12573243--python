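"""Exception hierarchy used across the package."""


class MetanetError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MetanetError, ValueError):
    """A function argument violates its contract."""


class InputError(MetanetError, ValueError):
    """Input data (image, clip, matrix) violates a precondition."""


class FormatError(MetanetError, ValueError):
    """A serialized container is malformed or incomplete."""


class ConfigurationError(MetanetError, ValueError):
    """A configuration value is missing, inconsistent, or unmapped."""


class TrainingError(MetanetError, RuntimeError):
    """Optimization diverged (NaN/Inf loss) or could not proceed."""


class StateError(MetanetError, RuntimeError):
    """An operation was called on an object in the wrong state."""
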