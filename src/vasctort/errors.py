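"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ``ValidationError``/``SchemaError``/
``ConfigError`` → exit 2 (bad inputs or configuration); partial per-image
failures → exit 1; anything else propagates.
"""


class VasctortError(Exception):
    """Base class for all package errors."""


class ValidationError(VasctortError):
    """An input violates a documented precondition or invariant."""


class SchemaError(ValidationError):
    """A tabular/sidecar file is missing required columns or keys."""


class FormatError(VasctortError):
    """A raster file cannot be interpreted as a single-channel mask."""


class ConfigError(VasctortError):
    """A run configuration contains unknown or invalid entries."""
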