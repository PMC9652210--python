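"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`AcetaverError`, so callers (and the CLI) can distinguish domain
failures from programming errors.
"""


class AcetaverError(Exception):
    """Base class for all acetaver errors."""


class FormatError(AcetaverError):
    """A file could not be parsed in the expected format."""


class ValidationError(AcetaverError):
    """An input object violates a documented invariant."""


class DegenerateInputError(AcetaverError):
    """Geometric input is degenerate (collinear, zero-length, too few points)."""


class FitError(AcetaverError):
    """A plane/circle fit could not be carried out or did not converge."""


class DetectionError(AcetaverError):
    """Automatic rim detection failed; a manual rim may be supplied instead."""


class EmptySliceError(AcetaverError):
    """The requested axial plane does not intersect the mesh."""


class ExtractionError(AcetaverError):
    """A slice landmark could not be snapped to any contour point."""


class DegeneratePoseError(AcetaverError):
    """A pose angle is undefined for this orientation (projection vanishes)."""
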