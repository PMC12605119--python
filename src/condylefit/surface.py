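"""Lofted ("swept") fitting surfaces and width/height semantic parameters.

A :class:`FeatureCurve` is a densely sampled smooth contour feature line whose
five key points are flagged among the samples.  Four curves of one side are
lofted into the bionic fitting surface: corresponding samples across the four
curves are joined by transverse chord-length cubic splines and the resulting
grid is tessellated into triangles (each quad split along its shortest
diagonal).  Every input curve sample is kept verbatim as a mesh vertex, so the
surface interpolates the curves exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.interpolate import CubicSpline

from .anatomy import LandmarkSet
from .errors import DegenerateLandmarksError, SelfIntersectionError

log = logging.getLogger(__name__)


@dataclass
class FeatureCurve:
    """Ordered samples of one finger contour feature line (mm)."""

    side: str
    finger_index: int
    points: np.ndarray  # (n, 3)
    knots: np.ndarray  # indices of the five key points among the samples
    flags: np.ndarray | None = None  # per-sample bool, True = projection fallback

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.knots = np.asarray(self.knots, dtype=int)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def key_points(self) -> np.ndarray:
        return self.points[self.knots]

    def arclengths(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def trimmed(self, first_knot: int = 1, last_knot: int = 3) -> "FeatureCurve":
        """Sub-curve between two key points (default: the joint-level span)."""
        i0, i1 = self.knots[first_knot], self.knots[last_knot]
        return FeatureCurve(
            self.side,
            self.finger_index,
            self.points[i0 : i1 + 1],
            self.knots[first_knot : last_knot + 1] - i0,
            flags=None if self.flags is None else self.flags[i0 : i1 + 1],
        )

    def resampled(self, n: int) -> "FeatureCurve":
        """Arc-length uniform resampling to exactly ``n`` points (key points kept)."""
        s = self.arclengths()
        target = np.linspace(0.0, s[-1], n)
        sk = s[self.knots]
        idx = np.round(sk / max(s[-1], 1e-12) * (n - 1)).astype(int)
        for j in range(1, len(idx)):  # keep key-point slots strictly increasing
            idx[j] = max(idx[j], idx[j - 1] + 1)
        idx = np.minimum(idx, n - 1)
        target[idx] = sk
        target = np.sort(target)
        knots = np.searchsorted(target, sk)
        pts = np.column_stack([np.interp(target, s, self.points[:, k]) for k in range(3)])
        return FeatureCurve(self.side, self.finger_index, pts, knots)


@dataclass(frozen=True)
class WidthParams:
    """Width/height semantics of the fitting surfaces (mm).

    Widths are coronal-plane projections of the medial/lateral landmark
    spans; heights are sagittal-plane projections of the high->low spans;
    ``W_ml`` is the intercondylar fossa width separating the two palms.
    """

    W_m: float
    W_l: float
    W_ml: float
    H_m: float
    H_l: float

    def __post_init__(self):
        for name in ("W_m", "W_l", "W_ml", "H_m", "H_l"):
            if getattr(self, name) <= 0:
                raise DegenerateLandmarksError(f"{name} must be positive")


@dataclass
class FittingSurface:
    """Lofted fitting surface of one side with its four boundary curves."""

    side: str
    mesh: trimesh.Trimesh
    curves: list = field(default_factory=list)
    transverse_extent: float = 0.0


def _project_out(v: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Remove the ``axis`` component of ``v`` (projection onto a plane)."""
    return v - (v @ axis) * axis


def measure_width_params(landmarks: LandmarkSet) -> WidthParams:
    """Width and height parameters measured from a landmark set.

    ``W_m``/``W_l`` are the medial/lateral spans projected onto the coronal
    plane (sagittal component removed); ``H_m``/``H_l`` the high->low spans
    projected onto the sagittal plane (coronal component removed); ``W_ml``
    the coronal distance between the fossa-facing extremes of the two sides.
    """
    f = landmarks.frame

    def _width(a, b):
        w = float(np.linalg.norm(_project_out(b - a, f.sagittal_axis)))
        if w < 1e-9:
            raise DegenerateLandmarksError("landmark span orthogonal to the coronal plane")
        return w

    def _height(a, b):
        h = float(np.linalg.norm(_project_out(b - a, f.coronal_axis)))
        if h < 1e-9:
            raise DegenerateLandmarksError("landmark span orthogonal to the sagittal plane")
        return h

    w_ml = float((landmarks.L_medial - landmarks.M_lateral) @ f.coronal_axis)
    if abs(w_ml) < 1e-9:
        raise DegenerateLandmarksError("zero intercondylar fossa width")
    return WidthParams(
        W_m=_width(landmarks.M_medial, landmarks.M_lateral),
        W_l=_width(landmarks.L_medial, landmarks.L_lateral),
        W_ml=abs(w_ml),
        H_m=_height(landmarks.M_high, landmarks.M_low),
        H_l=_height(landmarks.L_high, landmarks.L_low),
    )


def _check_transverse_order(sections: np.ndarray) -> None:
    """Reject lofts whose curves cross.

    For each transverse section the four points must appear in strictly
    increasing order along the first->last chord; a violation means two finger
    curves cross and the swept surface would self-intersect.
    """
    chord = sections[:, -1, :] - sections[:, 0, :]
    norm = np.linalg.norm(chord, axis=1)
    ok = norm > 1e-12
    if not ok.any():
        raise SelfIntersectionError("all transverse sections are degenerate")
    t = np.einsum("sij,sj->si", sections - sections[:, :1, :], chord) / np.maximum(
        norm[:, None] ** 2, 1e-30
    )
    if np.any(np.diff(t[ok], axis=1) <= -1e-9):
        raise SelfIntersectionError("finger curves cross; loft would self-intersect")


def build_fitting_surface(
    curves,
    widths: WidthParams | None = None,
    transverse_samples: int = 6,
) -> FittingSurface:
    """Loft four finger feature curves of one side into a fitting surface.

    ``transverse_samples`` is the number of tessellation intervals between
    consecutive finger curves.  Curves with mismatched sample counts are
    arc-length resampled to the largest count (logged as a warning).
    """
    curves = sorted(curves, key=lambda c: c.finger_index)
    if len(curves) != 4:
        raise ValueError("a fitting surface is lofted from exactly 4 finger curves")
    sides = {c.side for c in curves}
    if len(sides) != 1:
        raise ValueError("all curves must belong to the same side")
    side = curves[0].side
    counts = {len(c) for c in curves}
    if len(counts) > 1:
        n = max(counts)
        log.warning("loft curves have mismatched sample counts %s; resampling to %d", counts, n)
        curves = [c.resampled(n) if len(c) != n else c for c in curves]
    sections = np.stack([c.points for c in curves], axis=1)  # (n_samples, 4, 3)
    _check_transverse_order(sections)

    rows = []
    for sec in sections:
        chord = np.linalg.norm(np.diff(sec, axis=0), axis=1)
        t = np.concatenate([[0.0], np.cumsum(chord)])
        if t[-1] < 1e-12:  # all four curves coincide here
            rows.append(np.repeat(sec[:1], 3 * transverse_samples + 1, axis=0))
            continue
        keep = np.concatenate([[True], np.diff(t) > 1e-12])
        if keep.sum() < 2:
            rows.append(np.repeat(sec[:1], 3 * transverse_samples + 1, axis=0))
            continue
        spline = CubicSpline(t[keep], sec[keep], axis=0)
        ts = np.concatenate(
            [np.linspace(t[j], t[j + 1], transverse_samples + 1)[:-1] for j in range(3)]
            + [t[-1:]]
        )
        row = spline(ts)
        # keep the input curve samples exactly (spline evaluation noise-free)
        row[::transverse_samples] = sec
        rows.append(row)
    grid = np.stack(rows, axis=0)  # (n_samples, n_rows, 3)
    ns, nr = grid.shape[0], grid.shape[1]

    vid = np.arange(ns * nr).reshape(ns, nr)
    faces = []
    for i in range(ns - 1):
        for j in range(nr - 1):
            a, b, c, d = vid[i, j], vid[i + 1, j], vid[i + 1, j + 1], vid[i, j + 1]
            pa, pb, pc, pd = grid[i, j], grid[i + 1, j], grid[i + 1, j + 1], grid[i, j + 1]
            # split the quad along its shortest diagonal
            if np.linalg.norm(pa - pc) <= np.linalg.norm(pb - pd):
                faces.extend([[a, b, c], [a, c, d]])
            else:
                faces.extend([[a, b, d], [b, c, d]])
    mesh = trimesh.Trimesh(
        vertices=grid.reshape(-1, 3), faces=np.asarray(faces, dtype=int), process=False
    )
    mesh.update_faces(mesh.area_faces > 1e-12)

    extent = float(
        np.linalg.norm(sections[:, -1, :] - sections[:, 0, :], axis=1).max()
    )
    if widths is not None:
        target = widths.W_m if side == "medial" else widths.W_l
        # with the default 0.76 offset coefficients the loft extent is by
        # construction 0.76x the landmark width, so this is informational
        if abs(extent - target) > 0.02 * target:
            log.debug(
                "%s loft transverse extent %.2f mm differs from width parameter %.2f mm",
                side,
                extent,
                target,
            )
    return FittingSurface(side=side, mesh=mesh, curves=list(curves), transverse_extent=extent)
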