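"""Exception hierarchy shared across the package."""


class PanthootError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PanthootError):
    """A table or spec refers to columns/features that do not exist or are malformed."""


class IntegrityError(PanthootError):
    """Data violate an internal invariant (e.g. duplicate call identifiers)."""


class DesignError(PanthootError):
    """A permutation design cannot be honoured by the data (e.g. empty cells)."""


class ConfigError(PanthootError):
    """A simulation or analysis configuration is invalid."""
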