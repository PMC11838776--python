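"""Exception hierarchy.

All package-specific failures derive from :class:`PTSPOError` so callers can
catch one base class at pipeline level while tests discriminate subtypes.
"""


class PTSPOError(Exception):
    """Base class for all ptspo errors."""


class FormatError(PTSPOError):
    """Malformed tabular input (wrong columns, ragged rows, bad dtypes)."""


class ScheduleError(PTSPOError):
    """Invalid frame schedule (non-increasing starts, non-positive durations,
    overlapping frames, or frame count mismatch)."""


class DimensionError(PTSPOError):
    """Image / atlas / mask grids do not match."""


class ExtractionError(PTSPOError):
    """Blood-voxel extraction produced an empty candidate set."""


class DataError(PTSPOError):
    """Data values violate physical preconditions (e.g. strongly negative
    activities where non-negative concentrations are expected)."""


class FitError(PTSPOError):
    """Optimization failed to converge; carries diagnostic state."""


class SeparationError(FitError):
    """Perfect separation in an unpenalized logistic fit."""


class CollinearityError(FitError):
    """Rank-deficient design matrix."""


class ParameterError(PTSPOError):
    """Invalid model/kinetic parameter values (e.g. negative rate constants)."""


class CovariateError(PTSPOError):
    """Missing or invalid subject covariates."""


class GridError(PTSPOError):
    """Requested sample time outside the supported range of a schedule."""


class PredictionError(PTSPOError):
    """Prediction requested with missing features or normalization bounds."""


class InsufficientDataError(PTSPOError):
    """Too few samples/subjects/ROIs for the requested computation."""


class ConfigError(PTSPOError):
    """Invalid run or cohort configuration."""
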