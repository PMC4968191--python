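"""Exception hierarchy.

Every failure mode the library signals deliberately derives from
:class:`SpidiffError`, so callers can catch package errors without
swallowing genuine bugs.
"""


class SpidiffError(Exception):
    """Base class for all errors raised by spidiff."""


class InvalidGeometryError(SpidiffError):
    """Detector geometry violates an invariant (non-positive length, etc.)."""


class ResolutionUnreachableError(SpidiffError):
    """Requested resolution lies outside the physically reachable range."""


class InsufficientDarksError(SpidiffError):
    """Too few dark frames to estimate pedestal and read noise."""


class InsufficientStatisticsError(SpidiffError):
    """Too few flat-field samples per pixel for a gain fit."""


class InvalidGainError(SpidiffError):
    """Gain must be strictly positive."""


class NoBackgroundFramesError(SpidiffError):
    """No frames labelled blank; background average undefined."""


class InvalidOrientationError(SpidiffError):
    """Orientation quaternion is not normalized."""


class UnfittableFrameError(SpidiffError):
    """Frame has no unmasked photons; size fit undefined."""


class NotClassifiableError(SpidiffError):
    """Size fit did not converge; single-particle flag undefined."""


class InvalidCountError(SpidiffError):
    """Observed photon counts must be non-negative integers."""


class IncompatibleInputsError(SpidiffError):
    """Frame / model / mask shapes do not match."""


class DegenerateModelError(SpidiffError):
    """Model has zero surprise variance; z-score undefined."""


class InvalidSearchError(SpidiffError):
    """Empty or invalid search grid."""


class IncompatibleProfilesError(SpidiffError):
    """Radial profiles are binned differently and cannot be compared."""


class MalformedCxiError(SpidiffError):
    """HDF5 file does not follow the expected CXI layout."""


class MalformedSelectionError(SpidiffError):
    """Selection file lacks the timestamp dataset."""


class InvalidDatasetError(SpidiffError):
    """Inconsistent shapes or dtypes in a dataset to be written."""
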