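"""Exception hierarchy for the condylefit pipeline.

Every stage raises a subclass of :class:`CondylefitError` so callers (and the
CLI) can attach the stage name and a remediation hint without string matching.
"""


class CondylefitError(Exception):
    """Base class for all condylefit errors."""


class FrameUndefinedError(CondylefitError):
    """Mesh has too few non-coplanar vertices to define an anatomical frame."""


class MissingLandmarkError(CondylefitError):
    """A condyle region is empty; names the region in the message."""


class DegenerateLandmarksError(CondylefitError):
    """Landmark configuration has zero span or zero projected width."""


class InvalidParameterError(CondylefitError):
    """A design parameter is out of its valid range (e.g. d0 <= 0)."""


class DegeneratePolylineError(CondylefitError):
    """A contour polyline contains a zero-length segment."""


class OutOfRangeAngleError(CondylefitError):
    """Bending angle too close to 0/180 deg for the end-segment length formula."""


class SelfIntersectionError(CondylefitError):
    """Loft curves cross; the swept surface would self-intersect."""


class ProjectionFailedError(CondylefitError):
    """Too many curve samples missed the bone mesh during projection."""


class OpenContourError(CondylefitError):
    """Segmentation boundary does not close into a separating loop."""


class SeedRequiredError(CondylefitError):
    """Both sides of a cut are similar in area; an interior seed is needed."""


class EmptySelectionError(CondylefitError):
    """Segmentation boundary encloses no faces."""


class ReconstructionError(CondylefitError):
    """Submesh is non-manifold; attachment surface cannot be reconstructed."""


class InvalidShapeError(CondylefitError):
    """Synthetic condyle shape parameters are inconsistent."""
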