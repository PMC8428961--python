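"""Exception hierarchy shared across the package."""


class EelvkitError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(EelvkitError, ValueError):
    """A simulator or analysis configuration violates its invariants."""


class DataError(EelvkitError, ValueError):
    """Input signals or tables contain non-finite or malformed values."""


class ManeuverIncompleteError(EelvkitError):
    """A washin-washout maneuver lacks a required plateau or steady state."""


class DegenerateManeuverError(EelvkitError):
    """The FiO2 step produced too small a nitrogen-fraction change to divide by."""


class EstimationFailedError(EelvkitError):
    """EELV estimation produced a physically impossible result.

    Carries a ``diagnostics`` dict with the intermediate quantities.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class InsufficientDataError(EelvkitError, ValueError):
    """Too few observations for the requested statistic."""


class EmptyMaskError(EelvkitError, ValueError):
    """A CT lung mask selects no voxels."""


class InvalidMechanicsError(EelvkitError, ValueError):
    """Respiratory-mechanics inputs are physically inconsistent."""
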