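"""Exception hierarchy for ramanmix.

All package-specific failures derive from :class:`RamanMixError` so callers
can catch one base class at CLI boundaries.
"""


class RamanMixError(Exception):
    """Base class for all ramanmix errors."""


class InsufficientDataError(RamanMixError):
    """Too few points/frames/samples for the requested operation."""


class GridMismatchError(RamanMixError):
    """Spectra that must share a wavenumber grid do not."""


class DegenerateSpectrumError(RamanMixError):
    """A spectrum is unusable for the operation (e.g. all-zero for max-normalization)."""


class InvalidParameterError(RamanMixError):
    """A parameter violates its documented domain."""


class UnsupportedModeError(RamanMixError):
    """A vibrational mode lies outside the supported frequency range."""


class EmptyInputError(RamanMixError):
    """An operation received an empty collection."""


class UndefinedDihedralError(RamanMixError):
    """Collinear or coincident atoms make a dihedral angle undefined."""


class FlatRingError(RamanMixError):
    """All endocyclic torsions vanish; the pseudorotation phase is undefined."""


class MalformedTrajectoryError(RamanMixError):
    """A trajectory frame is missing atoms required by the torsion spec."""


class TraceMismatchError(RamanMixError):
    """Time series that must share timestep and length do not."""


class CubeParseError(RamanMixError):
    """A Gaussian CUBE file violates the format; the message names the record."""


class WindowError(RamanMixError):
    """A wavenumber window does not overlap the spectrum grid."""


class NonConvergenceError(RamanMixError):
    """Every optimizer restart failed; diagnostics attached.

    Attributes
    ----------
    diagnostics : list
        Per-restart status messages from the optimizer.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class DegenerateFitError(RamanMixError):
    """Fitted weights cannot be normalized into populations (sum <= 0)."""


class TimestepError(RamanMixError):
    """Frame interval too coarse for the requested transition rates."""
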