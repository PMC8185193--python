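"""Exception types shared across the package."""


class RtmenoError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(RtmenoError, ValueError):
    """Input data violates a documented invariant (bad dose, volume, label...)."""


class SchemaError(ValidationError):
    """A tabular input is missing a required column or has the wrong layout."""


class ConfigurationError(RtmenoError, ValueError):
    """A simulation or run configuration is internally inconsistent."""
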