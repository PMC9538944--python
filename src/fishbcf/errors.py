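"""Exception hierarchy shared across the package."""


class FishBcfError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(FishBcfError, ValueError):
    """A value violates a precondition (non-positive concentration, bad rate, ...)."""


class InsufficientDataError(FishBcfError, ValueError):
    """Too few usable observations for the requested fit or summary."""


class ConfigurationError(FishBcfError, ValueError):
    """A parameter set is incomplete or outside its validated domain."""


class SchemaError(FishBcfError, ValueError):
    """A tabular input does not match the expected schema."""
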