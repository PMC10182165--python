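"""Exception hierarchy. Every domain failure raises a subclass of TSRError so
callers (and the CLI) can distinguish user/data errors from bugs."""


class TSRError(Exception):
    """Base class for all package errors."""


class SchemaError(TSRError):
    """Feature columns or array dimensions disagree with the stream schema."""


class DataError(TSRError):
    """A table violates an ordering or uniqueness invariant."""


class ConsistencyError(TSRError):
    """Features and labels tables disagree about the patient set."""


class MissingDataError(TSRError):
    """Empty cells / NaNs in an ingested table; missingness is rejected, not imputed."""


class DegenerateFeatureError(TSRError):
    """A feature is constant on the fitting subset and cannot be standardized."""


class TrainingError(TSRError):
    """The training set is unusable (e.g. single-class)."""


class ValidationError(TSRError):
    """An argument or configuration value is out of range."""
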