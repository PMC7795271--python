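"""Exception hierarchy shared across the pipeline stages."""


class RepcountError(Exception):
    """Base class for all package errors."""


class InvalidInputError(RepcountError, ValueError):
    """A data object violates a precondition (empty series, bad shape, ...)."""


class InvalidParameterError(RepcountError, ValueError):
    """A tuning parameter is outside its admissible range."""


class ConfigurationError(RepcountError, ValueError):
    """A registry, template store or pipeline configuration is inconsistent."""
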