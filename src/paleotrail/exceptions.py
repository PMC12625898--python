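"""Exception hierarchy for paleotrail.

All errors derive from :class:`PaleotrailError` so callers can catch the
package's failures with a single except clause; subclasses additionally
derive from the closest builtin (ValueError, KeyError, IOError) so generic
handling keeps working.
"""


class PaleotrailError(Exception):
    """Base class for all paleotrail errors."""


class ConfigurationError(PaleotrailError, ValueError):
    """A configuration object or parameter block is invalid."""


class GenerationError(PaleotrailError, ValueError):
    """A synthetic-data generator cannot satisfy its constraints."""


class TaxonLookupError(PaleotrailError, KeyError):
    """A taxon label is absent from a marker table."""


class CurveFormatError(PaleotrailError, ValueError):
    """A calibration-curve file is malformed or non-monotone."""


class OutOfCurveError(PaleotrailError, ValueError):
    """A radiocarbon determination lies entirely outside the curve support."""


class AlignmentLookupError(PaleotrailError, KeyError):
    """A sequence label is absent from an alignment."""


class SamplingError(PaleotrailError, ValueError):
    """An ensemble member cannot be drawn (e.g. a box holds too few records)."""


class InsufficientSampleError(PaleotrailError, ValueError):
    """Too few rows to estimate a 2-D climate envelope."""


class GridDomainError(PaleotrailError, ValueError):
    """A point or box falls outside the climate grid."""


class EnsembleRunError(PaleotrailError, RuntimeError):
    """Too many ensemble members failed for the run to be trusted."""


class ValidationError(PaleotrailError, ValueError):
    """A run configuration failed validation; message lists the fields."""
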