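"""Exception hierarchy shared across the package."""


class ExplantQuantError(Exception):
    """Base class for all errors raised by explantquant."""


class ValidationError(ExplantQuantError, ValueError):
    """A configuration value or function argument violates its contract."""


class SchemaError(ExplantQuantError):
    """A table does not match the expected column schema."""


class MissingColumnError(SchemaError):
    """A required column is absent from an input table."""


class NonNumericColumnError(SchemaError):
    """A column that must be numeric contains non-numeric values."""


class DuplicateIdError(SchemaError):
    """nucleus_id values are not unique within a sample table."""


class UnknownConfigKeyError(ExplantQuantError):
    """A config file contains a key the schema does not define."""


class EmptyBackgroundBandError(ExplantQuantError):
    """No nuclei fall in the background distance band and no explicit
    background value was supplied."""
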