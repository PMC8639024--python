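"""Exception hierarchy shared across the surveillance pipeline."""


class AsdsurvError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AsdsurvError):
    """A generator or analysis configuration violates its invariants."""


class ConsistencyError(AsdsurvError):
    """Inputs that must describe the same children or population do not."""


class DataError(AsdsurvError):
    """A referenced entity (tract, denominator cell) is missing or malformed."""


class ValidationError(AsdsurvError):
    """An operation received inputs outside its documented domain."""
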