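"""Exception types shared across the package."""


class SpatialTilError(Exception):
    """Base class for all package errors."""


class SchemaError(SpatialTilError):
    """An input table violates the documented CSV schema."""


class ConfigurationError(SpatialTilError):
    """A configuration value is invalid (nonpositive rate, bad mode, ...)."""


class ConvergenceError(SpatialTilError):
    """A model fit failed to converge or the likelihood is monotone
    (complete separation); never silently ignored."""
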