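"""Exception hierarchy shared across the package."""


class OptoconnError(Exception):
    """Base class for all package-specific errors."""


class FormatError(OptoconnError):
    """A file or container does not conform to the expected layout."""


class DataError(OptoconnError):
    """Input data violate an invariant (non-positive intensity, NaNs, ...)."""


class ConfigError(OptoconnError):
    """A configuration value is invalid (singular extinction pair, bad DPF, ...)."""


class SpecError(OptoconnError):
    """A simulation/cohort specification is inconsistent."""
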