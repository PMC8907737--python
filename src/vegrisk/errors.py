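"""Exception hierarchy shared across the pipeline stages."""


class VegriskError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(VegriskError, ValueError):
    """Invalid scenario or run configuration (non-positive parameter, empty grid, ...)."""


class SchemaError(VegriskError, ValueError):
    """Input file violates the expected schema (missing column, non-numeric cell,
    non-positive limit or consumption). The message names the offending row/column."""


class DataError(VegriskError, ValueError):
    """Structurally valid input that cannot be processed (nondetect without an LOD,
    combination missing a consumption entry or category limit)."""


class DomainError(VegriskError, ValueError):
    """Numeric argument outside an operation's mathematical domain."""
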