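"""Bionic finger contour feature lines.

Each condyle carries four "finger" contour feature lines, one per finger of
the hand analogy.  A line is a five-point chain: start, three joint-level key
points and an end.  The joint-level points are anchored at the condyle's
high / extreme / low landmarks; successive fingers are offset from those
anchors along the anterior-posterior axis by distances that scale with the
condylar span and six dimensionless coefficients (three per side).  The chain
is parameterized by three interior bending angles (degrees) and four phalanx
segment lengths (mm); the parameterization is invertible, so a chain can also
be forward-constructed from a parameter row.

Conventions adopted here (see docs/methods.md for the reasoning):

* Offsets displace medial fingers posteriorly and lateral fingers anteriorly
  (the sides' negative/positive offset directions), so the four fingers of a
  side drape across the condyle's anterior-posterior depth.
* The start/end "osteotomy" plane of a line lies parallel to the adjacent
  phalanx segment at perpendicular distance ``d0`` on the outward (convex)
  side of the chain; with that convention the end-segment length formula
  ``m = d0 / cos(angle - 90 deg)`` holds for any end-segment slant.
* Angles are degrees at every public boundary, radians internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .anatomy import AnatomicalFrame, LandmarkSet
from .errors import (
    DegenerateLandmarksError,
    DegeneratePolylineError,
    InvalidParameterError,
    OutOfRangeAngleError,
)
from .surface import FeatureCurve, WidthParams

DEFAULT_COEFFICIENT = 0.76  # population-average calibrated value
DEFAULT_END_ANGLE = 135.0  # start/end bending angle used when no hint is given

_EPS = 1e-9


@dataclass(frozen=True)
class CoefficientSet:
    """The six dimensionless offset scaling coefficients.

    ``delta1..3`` scale the medial offsets, ``epsilon1..3`` the lateral ones.
    The calibrated population-average default is 0.76 for all six.
    """

    delta1: float = DEFAULT_COEFFICIENT
    delta2: float = DEFAULT_COEFFICIENT
    delta3: float = DEFAULT_COEFFICIENT
    epsilon1: float = DEFAULT_COEFFICIENT
    epsilon2: float = DEFAULT_COEFFICIENT
    epsilon3: float = DEFAULT_COEFFICIENT

    def __post_init__(self):
        if any(v <= 0 for v in self.as_array()):
            raise InvalidParameterError("all scaling coefficients must be positive")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.delta1, self.delta2, self.delta3, self.epsilon1, self.epsilon2, self.epsilon3]
        )

    def side(self, side: str) -> tuple[float, float, float]:
        if side == "medial":
            return (self.delta1, self.delta2, self.delta3)
        if side == "lateral":
            return (self.epsilon1, self.epsilon2, self.epsilon3)
        raise ValueError(f"unknown side {side!r}")

    @classmethod
    def from_array(cls, values) -> "CoefficientSet":
        v = [float(x) for x in values]
        return cls(*v)


@dataclass(frozen=True)
class OffsetTriple:
    """Offsets (mm) of one finger's three joint-level key points."""

    h1: float
    h2: float
    h3: float

    def as_array(self) -> np.ndarray:
        return np.array([self.h1, self.h2, self.h3])


@dataclass(frozen=True)
class BendingAngles:
    """Interior bending angles (degrees) at the three joint-level key points."""

    a1: float
    a2: float
    a3: float

    def __post_init__(self):
        for v in (self.a1, self.a2, self.a3):
            if not (0.0 < v <= 180.0):
                raise InvalidParameterError(f"bending angle {v} outside (0, 180]")

    def as_tuple(self):
        return (self.a1, self.a2, self.a3)


@dataclass(frozen=True)
class SegmentLengths:
    """Lengths (mm) of the four phalanx segments of one finger line."""

    m1: float
    m2: float
    m3: float
    m4: float

    def __post_init__(self):
        for v in self.as_tuple():
            if v <= 0:
                raise InvalidParameterError(f"segment length {v} must be positive")

    def as_tuple(self):
        return (self.m1, self.m2, self.m3, self.m4)


@dataclass(frozen=True)
class FingerPolyline:
    """Five-point contour chain of one finger (start, k1, k2, k3, end)."""

    side: str
    finger_index: int
    start: np.ndarray
    k1: np.ndarray
    k2: np.ndarray
    k3: np.ndarray
    end: np.ndarray

    def __post_init__(self):
        for name in ("start", "k1", "k2", "k3", "end"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        pts = self.points
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg <= _EPS):
            raise DegeneratePolylineError(
                f"finger {self.finger_index} ({self.side}): zero-length phalanx segment"
            )

    @property
    def points(self) -> np.ndarray:
        return np.stack([self.start, self.k1, self.k2, self.k3, self.end])

    def transformed(self, rotation, translation) -> "FingerPolyline":
        r = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        return FingerPolyline(
            self.side,
            self.finger_index,
            *[r @ p + t for p in self.points],
        )


@dataclass(frozen=True)
class BionicParams:
    """One design instance: per-finger bending/length rows, widths and d0."""

    medial: tuple  # four (BendingAngles, SegmentLengths) pairs
    lateral: tuple
    widths: WidthParams | None = None
    d0: float = 5.0

    def __post_init__(self):
        if len(self.medial) != 4 or len(self.lateral) != 4:
            raise InvalidParameterError("exactly four finger entries per side")
        if self.d0 <= 0:
            raise InvalidParameterError("d0 must be positive")

    @classmethod
    def from_rows(cls, medial_row, lateral_row, widths=None, d0: float = 5.0) -> "BionicParams":
        """Replicate one (angles, lengths) row pair to all four fingers.

        A design group prints one parameter row per side; it is treated as the
        index-finger row, with fingers 2-4 derived geometrically via offsets.
        """
        return cls(medial=tuple([medial_row] * 4), lateral=tuple([lateral_row] * 4),
                   widths=widths, d0=d0)


def _row(angles, lengths):
    return (BendingAngles(*angles), SegmentLengths(*lengths))


#: Reference design groups (angles deg; lengths mm; widths mm): the four
#: parameter sets used for the package's worked examples and validation runs.
DESIGN_GROUPS = {
    1: {
        "medial": _row((140.01, 122.45, 143.48), (10.74, 30.86, 24.66, 9.15)),
        "lateral": _row((133.86, 109.67, 157.53), (16.99, 26.09, 18.39, 12.11)),
        "W_m": 21.20,
        "W_l": 22.80,
    },
    2: {
        "medial": _row((143.91, 141.21, 144.32), (10.74, 31.92, 21.17, 10.74)),
        "lateral": _row((145.87, 153.05, 129.17), (10.75, 29.86, 20.22, 8.87)),
        "W_m": 21.34,
        "W_l": 23.30,
    },
    3: {
        "medial": _row((138.79, 124.03, 141.58), (10.74, 32.86, 20.58, 10.74)),
        "lateral": _row((134.20, 129.96, 141.37), (8.86, 31.78, 22.14, 6.87)),
        "W_m": 21.61,
        "W_l": 24.62,
    },
    4: {
        "medial": _row((133.20, 124.03, 138.19), (10.74, 32.85, 20.57, 10.74)),
        "lateral": _row((144.10, 151.29, 129.17), (10.74, 28.52, 20.22, 8.86)),
        "W_m": 21.61,
        "W_l": 23.10,
    },
}


def design_group_params(group: int, d0: float = 5.0) -> BionicParams:
    """The :class:`BionicParams` of one reference design group (1-4)."""
    g = DESIGN_GROUPS[group]
    return BionicParams.from_rows(g["medial"], g["lateral"], d0=d0)


# ---------------------------------------------------------------------------
# offsets and key-point placement
# ---------------------------------------------------------------------------


def compute_offsets(
    landmarks: LandmarkSet,
    coeffs: CoefficientSet,
    side: str,
    finger_index: int,
    span_convention: str = "as-published",
) -> OffsetTriple:
    """Joint-level offsets of one finger line.

    ``h_k = (finger_index - 1) * span_k / 3 * coefficient_k``.

    For the lateral side every level uses the lateral landmark span.  For the
    medial side the published formula mixes spans: level 1 uses the medial
    span while levels 2-3 use the lateral span; ``span_convention="same-side"``
    switches levels 2-3 to the medial span instead.
    """
    if finger_index not in (1, 2, 3, 4):
        raise ValueError("finger_index must be 1..4")
    if span_convention not in ("as-published", "same-side"):
        raise ValueError(f"unknown span convention {span_convention!r}")
    span_m = float(np.linalg.norm(landmarks.M_lateral - landmarks.M_medial))
    span_l = float(np.linalg.norm(landmarks.L_lateral - landmarks.L_medial))
    if side == "medial":
        spans = (span_m, span_l, span_l) if span_convention == "as-published" else (span_m,) * 3
    elif side == "lateral":
        spans = (span_l,) * 3
    else:
        raise ValueError(f"unknown side {side!r}")
    if min(spans) <= _EPS:
        raise DegenerateLandmarksError(f"degenerate {side} landmark span")
    c = coeffs.side(side)
    h = [(finger_index - 1) * spans[k] / 3.0 * c[k] for k in range(3)]
    return OffsetTriple(*h)


def _chain_plane_normal(k1, k2, k3, frame: AnatomicalFrame | None):
    w = np.cross(k2 - k1, k3 - k2)
    n = np.linalg.norm(w)
    if n > _EPS:
        return w / n
    # collinear joints: fall back to a plane containing the chain and a frame axis
    chord = k3 - k1
    for ref in ([0.0, 1.0, 0.0] if frame is None else [frame.sagittal_axis, frame.coronal_axis],
                [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]):
        for r in np.atleast_2d(np.asarray(ref, float)):
            w = np.cross(chord, r)
            n = np.linalg.norm(w)
            if n > _EPS:
                return w / n
    raise DegeneratePolylineError("cannot define a chain plane")


def _end_point(joint, inner, other_joint, w, d0, angle_deg):
    """Start/end point on the osteotomy plane beyond a terminal joint.

    The plane is parallel to the adjacent phalanx segment (joint->inner) at
    perpendicular distance ``d0`` on the outward side of the chain; the point
    is slanted within the chain plane so the bending angle at the joint equals
    ``angle_deg``.
    """
    u = inner - joint
    u = u / np.linalg.norm(u)
    n = np.cross(w, u)
    n = n / np.linalg.norm(n)
    g = (joint + inner + other_joint) / 3.0
    outward = joint - g
    if float(n @ outward) < 0.0:
        n = -n
    t = d0 * math.tan(math.radians(angle_deg - 90.0))
    return joint + d0 * n - t * u


def place_key_points(
    landmarks: LandmarkSet,
    offsets: OffsetTriple,
    side: str,
    finger_index: int,
    d0: float,
    angles_hint: BendingAngles | None = None,
) -> FingerPolyline:
    """Place the five key points of one finger contour line.

    Joint-level points sit at the side's high / extreme / low landmarks,
    displaced along the side's offset direction (medial fingers posteriorly,
    lateral fingers anteriorly) by the finger's offsets.  Start/end points lie
    on the osteotomy plane at perpendicular distance ``d0`` beyond the first
    and third joints; their slant uses ``angles_hint`` (first and third
    angles) or a 135 deg default.
    """
    if d0 <= 0:
        raise InvalidParameterError("d0 must be positive")
    anchors = landmarks.side(side)
    frame = landmarks.frame
    sign = -1.0 if side == "medial" else 1.0
    direction = sign * frame.sagittal_axis
    h = offsets.as_array()
    k1 = anchors["high"] + h[0] * direction
    k2 = anchors["extreme"] + h[1] * direction
    k3 = anchors["low"] + h[2] * direction
    w = _chain_plane_normal(k1, k2, k3, frame)
    a1 = angles_hint.a1 if angles_hint is not None else DEFAULT_END_ANGLE
    a3 = angles_hint.a3 if angles_hint is not None else DEFAULT_END_ANGLE
    start = _end_point(k1, k2, k3, w, d0, a1)
    end = _end_point(k3, k2, k1, w, d0, a3)
    return FingerPolyline(side, finger_index, start, k1, k2, k3, end)


# ---------------------------------------------------------------------------
# parameter extraction and inversion
# ---------------------------------------------------------------------------


def _interior_angle(p, q, r) -> float:
    """Interior angle at q (degrees) between segments q->p and q->r."""
    u = p - q
    v = r - q
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu <= _EPS or nv <= _EPS:
        raise DegeneratePolylineError("zero-length segment at a joint")
    c = float(u @ v) / (nu * nv)
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def compute_bending_angles(polyline: FingerPolyline) -> BendingAngles:
    """The three interior bending angles (degrees) of a finger chain."""
    p = polyline.points
    return BendingAngles(
        a1=_interior_angle(p[0], p[1], p[2]),
        a2=_interior_angle(p[1], p[2], p[3]),
        a3=_interior_angle(p[2], p[3], p[4]),
    )


def compute_segment_lengths(
    polyline: FingerPolyline,
    d0: float | None = None,
    angles: BendingAngles | None = None,
) -> SegmentLengths:
    """The four phalanx segment lengths (mm) of a finger chain.

    The middle lengths are Euclidean joint distances.  With an explicit
    ``d0`` the end lengths follow the osteotomy relation
    ``m = d0 / cos(angle - 90 deg)``; with ``d0=None`` they are the Euclidean
    end-segment lengths (the two coincide when the chain was built with the
    package's osteotomy-plane convention).
    """
    p = polyline.points
    m2 = float(np.linalg.norm(p[2] - p[1]))
    m3 = float(np.linalg.norm(p[3] - p[2]))
    if d0 is None:
        m1 = float(np.linalg.norm(p[1] - p[0]))
        m4 = float(np.linalg.norm(p[4] - p[3]))
    else:
        if d0 <= 0:
            raise InvalidParameterError("d0 must be positive")
        if angles is None:
            angles = compute_bending_angles(polyline)
        out = []
        for a in (angles.a1, angles.a3):
            c = math.cos(math.radians(a - 90.0))
            if abs(c) < 1e-6:
                raise OutOfRangeAngleError(
                    f"bending angle {a} deg leaves the end segment unbounded"
                )
            out.append(d0 / c)
        m1, m4 = out
    return SegmentLengths(m1, m2, m3, m4)


def forward_construct(
    angles: BendingAngles,
    lengths: SegmentLengths,
    frame: AnatomicalFrame | None = None,
    anchor=(0.0, 0.0, 0.0),
    plane_normal=(0.0, 0.0, 1.0),
    side: str = "medial",
    finger_index: int = 1,
) -> FingerPolyline:
    """Planar five-point chain realizing given bending angles and lengths.

    The chain is confined to the plane through ``anchor`` with normal
    ``plane_normal``; every joint turns toward the same half-plane (convex
    chain), so recomputing angles and lengths from the result reproduces the
    inputs exactly.
    """
    n = np.asarray(plane_normal, dtype=float)
    nn = np.linalg.norm(n)
    if nn < _EPS:
        raise InvalidParameterError("zero plane normal")
    n = n / nn
    ref = np.array([1.0, 0.0, 0.0])
    if abs(float(ref @ n)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - (ref @ n) * n
    u = u / np.linalg.norm(u)
    v = np.cross(n, u)

    heading = 0.0
    pts = [np.asarray(anchor, dtype=float)]
    turn_after = (angles.a1, angles.a2, angles.a3, None)
    for m, a in zip(lengths.as_tuple(), turn_after):
        d = math.cos(heading) * u + math.sin(heading) * v
        pts.append(pts[-1] + m * d)
        if a is not None:
            heading += math.pi - math.radians(a)
    return FingerPolyline(side, finger_index, *pts)


def fit_feature_curve(polyline: FingerPolyline, samples_per_segment: int = 10) -> FeatureCurve:
    """Smooth interpolating curve through the five key points.

    Chord-length parameterized cubic spline; the returned dense polyline
    contains the key points verbatim among its samples (``samples_per_segment``
    intervals per phalanx segment).
    """
    if samples_per_segment < 2:
        raise InvalidParameterError("samples_per_segment must be >= 2")
    p = polyline.points
    chord = np.linalg.norm(np.diff(p, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(chord)])
    spline = CubicSpline(t, p, axis=0)
    ts = np.concatenate(
        [np.linspace(t[j], t[j + 1], samples_per_segment + 1)[:-1] for j in range(4)] + [t[-1:]]
    )
    samples = spline(ts)
    knots = np.arange(0, 4 * samples_per_segment + 1, samples_per_segment)
    samples[knots] = p  # key points exact
    return FeatureCurve(polyline.side, polyline.finger_index, samples, knots)
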