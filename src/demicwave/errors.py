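"""Exception hierarchy for the demicwave pipeline."""


class DemicwaveError(Exception):
    """Base class for all package errors."""


class NoDatesError(DemicwaveError):
    """Raised when a filtering step leaves no radiocarbon dates."""


class CalibrationRangeError(DemicwaveError):
    """Raised when a determination falls outside the calibration curve support."""


class ParameterError(DemicwaveError, ValueError):
    """Raised for invalid user-supplied parameters."""


class RasterError(DemicwaveError):
    """Raised for malformed or unusable rasters."""


class UnreachableError(DemicwaveError):
    """Raised when an origin or destination cannot be reached on the cost graph."""


class NoSitesError(DemicwaveError):
    """Raised when a site-selection step receives or produces no sites."""


class SingularFitError(DemicwaveError):
    """Raised when a regression design matrix is singular (no variance in x)."""


class FrontNotAdvancingError(DemicwaveError):
    """Raised when a fitted slope is non-positive, so a front speed is undefined."""
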