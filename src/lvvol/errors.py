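"""Exception hierarchy for lvvol.

All package-specific failures derive from :class:`LVVolError` so callers can
catch one base class at pipeline boundaries.
"""


class LVVolError(Exception):
    """Base class for all lvvol errors."""


class BorderValidationError(LVVolError):
    """A border polygon violates a structural invariant (too few vertices,
    self-intersection, zero area, bad landmark indices)."""


class LandmarkError(LVVolError):
    """Apex or mitral-annulus landmarks are missing or inconsistent."""


class GeometryError(LVVolError):
    """A geometric computation is undefined for the given input
    (zero-length long axis, centroid outside the polygon, ...)."""


class ConfigurationError(LVVolError):
    """An invalid configuration value (split fraction, layer depth, ...)."""


class SingularFitError(LVVolError):
    """The regression design matrix is rank deficient or underdetermined."""


class DivergenceError(LVVolError):
    """Network training produced a non-finite loss."""


class UndefinedStatisticError(LVVolError):
    """An agreement statistic is undefined for the input (constant series)."""


class AlignmentError(LVVolError):
    """Method and reference series do not cover the same frames."""


class ShapeRejectionError(LVVolError):
    """Synthetic shape parameters produced an invalid (self-intersecting)
    contour."""


class DegenerateCycleWarning(UserWarning):
    """A volume series with no systolic excursion (EDV == ESV)."""
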