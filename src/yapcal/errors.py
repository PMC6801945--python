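"""Exception hierarchy for the calibration pipeline."""


class YapcalError(Exception):
    """Base class for all package errors."""


class ConfigurationError(YapcalError):
    """A configuration object failed validation; the message names the field."""


class DataError(YapcalError):
    """Malformed or inconsistent input data (duplicate epochs, negative METs, ...)."""


class ModelError(YapcalError):
    """The regression design is deficient (singular, a stage absent, ...)."""


class InputError(YapcalError):
    """A pipeline input file is missing, unreadable, or schema-invalid."""
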