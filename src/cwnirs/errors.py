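"""Exception hierarchy for the cwnirs package.

Every error raised by the library derives from :class:`CWNIRSError` so
callers can catch the whole family with one clause; the subclasses mirror
the distinct failure contracts of the analysis stages (table lookups, grid
alignment, inversion conditioning, file parsing, study bookkeeping).
"""


class CWNIRSError(Exception):
    """Base class for all cwnirs errors."""


class UnknownChromophoreError(CWNIRSError, KeyError):
    """A chromophore name is not present in the extinction table."""


class WavelengthRangeError(CWNIRSError, ValueError):
    """A wavelength falls outside the span of a lookup table (no extrapolation)."""


class GridAlignmentError(CWNIRSError, ValueError):
    """Two spectra that must share a wavelength grid do not."""


class DomainError(CWNIRSError, ValueError):
    """Input values outside the mathematical domain (e.g. non-positive intensity)."""


class WavelengthResolutionError(CWNIRSError, ValueError):
    """A requested analysis wavelength is farther than the snap tolerance from any grid point."""


class ConditioningError(CWNIRSError, ValueError):
    """The extinction design matrix is singular or too ill-conditioned to invert."""


class SaturationUndefinedError(CWNIRSError, ZeroDivisionError):
    """Total hemoglobin is zero after clamping; StO2 is undefined."""


class BaselineMissingError(CWNIRSError, ValueError):
    """No baseline (day-0, pre-surgery) acquisition exists for a differential series."""


class ParseError(CWNIRSError, ValueError):
    """A study file on disk is malformed; the message names the file and line."""


class DegenerateRowError(CWNIRSError, ValueError):
    """A spectrum row has zero variance and cannot be variance-normalized."""


class InsufficientDataError(CWNIRSError, ValueError):
    """Too few rows to define a robust statistic."""


class GroupingError(CWNIRSError, ValueError):
    """A requested metadata group or timepoint is empty or absent."""
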