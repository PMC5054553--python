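"""Exception types shared across the pipeline."""


class Ki67Error(Exception):
    """Base class for all package-specific errors."""


class ConfigError(Ki67Error):
    """A configuration value is outside its documented range."""


class ValidationError(Ki67Error):
    """An input object violates its invariants (names the offending element)."""


class ShapeError(Ki67Error):
    """Rasters that must be aligned have mismatched shapes."""
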