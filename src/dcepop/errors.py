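"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`DcepopError`
so callers can catch package failures without masking programming errors.
"""


class DcepopError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DcepopError):
    """A model/topology/sampler configuration is inconsistent or incomplete."""


class DataError(DcepopError):
    """Input data violate the event-record contract."""


class SchemaError(DataError):
    """An input table is missing required columns or has wrong dtypes."""


class DerivationError(DcepopError):
    """A derived quantity (e.g. a distribution volume) cannot be computed."""


class NumericError(DcepopError):
    """A numeric evaluation produced non-finite or invalid values."""


class EstimationError(DcepopError):
    """An estimation stage diverged or was asked for before it ran."""


class StateError(DcepopError):
    """An object is not in the state required for the requested operation."""


class ComparisonError(DcepopError):
    """Two fits cannot be compared (e.g. different datasets)."""
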