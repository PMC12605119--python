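"""Anatomical frame, condylar landmarks and the surface-mesh container.

The distal femur is handled as a plain triangle surface mesh (a
:class:`trimesh.Trimesh`, coordinates in mm).  Quads in input files are
triangulated on load.  An :class:`AnatomicalFrame` is a right-handed
orthonormal triad: the *coronal* axis runs medial->lateral (the medial condyle
lies on its negative side), the *sagittal* axis runs posterior->anterior and
the *vertical* axis points toward the proximal ("high") direction.  The
coronal plane is spanned by (coronal, vertical), the sagittal plane by
(sagittal, vertical).

Landmark detection is purely extremal: within each condyle region the vertex
extreme along the relevant frame axis wins, with ties broken by the lowest
vertex index so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .errors import FrameUndefinedError, MissingLandmarkError

_ORTHO_TOL = 1e-9

LANDMARK_NAMES = (
    "M_medial",
    "M_lateral",
    "M_high",
    "M_low",
    "L_medial",
    "L_lateral",
    "L_high",
    "L_low",
)


@dataclass(frozen=True)
class AnatomicalFrame:
    """Right-handed orthonormal anatomical coordinate triad (mm)."""

    origin: np.ndarray
    coronal_axis: np.ndarray  # medial -> lateral
    sagittal_axis: np.ndarray  # posterior -> anterior
    vertical_axis: np.ndarray  # distal -> proximal ("high")

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        axes = []
        for name in ("coronal_axis", "sagittal_axis", "vertical_axis"):
            ax = np.asarray(getattr(self, name), dtype=float)
            if abs(np.linalg.norm(ax) - 1.0) > 1e-6:
                raise FrameUndefinedError(f"{name} is not unit length")
            axes.append(ax)
            object.__setattr__(self, name, ax)
        c, s, v = axes
        for a, b in ((c, s), (c, v), (s, v)):
            if abs(float(a @ b)) > 1e-6:
                raise FrameUndefinedError("frame axes are not orthogonal")
        if np.linalg.det(np.stack(axes)) < 0.0:
            raise FrameUndefinedError("frame axes are left-handed")

    @property
    def axes(self) -> np.ndarray:
        """Axes as rows (coronal, sagittal, vertical)."""
        return np.stack([self.coronal_axis, self.sagittal_axis, self.vertical_axis])

    def coords(self, points: np.ndarray) -> np.ndarray:
        """Frame coordinates (coronal, sagittal, vertical) of world points."""
        return (np.atleast_2d(points) - self.origin) @ self.axes.T

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AnatomicalFrame":
        r = np.asarray(rotation, float)
        return AnatomicalFrame(
            origin=r @ self.origin + np.asarray(translation, float),
            coronal_axis=r @ self.coronal_axis,
            sagittal_axis=r @ self.sagittal_axis,
            vertical_axis=r @ self.vertical_axis,
        )


def orthonormal_frame(origin, coronal, sagittal, vertical=None) -> AnatomicalFrame:
    """Build a frame from (possibly imperfect) axis hints.

    The coronal hint is kept, the sagittal hint is Gram-Schmidt projected, and
    the vertical axis is recomputed as coronal x sagittal so the triad is
    exactly right-handed.  ``vertical`` is only used to disambiguate the sign
    of the recomputed axis.
    """
    c = np.asarray(coronal, float)
    nc = np.linalg.norm(c)
    if nc < _ORTHO_TOL:
        raise FrameUndefinedError("zero coronal axis hint")
    c = c / nc
    s = np.asarray(sagittal, float)
    s = s - (s @ c) * c
    ns = np.linalg.norm(s)
    if ns < _ORTHO_TOL:
        raise FrameUndefinedError("sagittal hint parallel to coronal hint")
    s = s / ns
    v = np.cross(c, s)
    if vertical is not None and float(np.asarray(vertical, float) @ v) < 0.0:
        s, v = -s, -v
    return AnatomicalFrame(np.asarray(origin, float), c, s, v)


@dataclass(frozen=True)
class LandmarkSet:
    """The eight condylar extrema (mm) plus the anatomical frame.

    ``M_*`` live on the medial condyle, ``L_*`` on the lateral condyle;
    medial/lateral are coronal-axis extremes within the region, high/low are
    vertical-axis extremes.
    """

    M_medial: np.ndarray
    M_lateral: np.ndarray
    M_high: np.ndarray
    M_low: np.ndarray
    L_medial: np.ndarray
    L_lateral: np.ndarray
    L_high: np.ndarray
    L_low: np.ndarray
    frame: AnatomicalFrame

    def __post_init__(self):
        for name in LANDMARK_NAMES:
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))

    def point(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def side(self, side: str) -> dict:
        """The (high, extreme, low) landmarks of one side, keyed by level."""
        if side == "medial":
            return {"high": self.M_high, "extreme": self.M_medial, "low": self.M_low}
        if side == "lateral":
            return {"high": self.L_high, "extreme": self.L_lateral, "low": self.L_low}
        raise ValueError(f"unknown side {side!r}")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LandmarkSet":
        r = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        kw = {name: r @ getattr(self, name) + t for name in LANDMARK_NAMES}
        return LandmarkSet(frame=self.frame.transformed(r, t), **kw)

    def to_dict(self) -> dict:
        d = {name: getattr(self, name).tolist() for name in LANDMARK_NAMES}
        d["frame"] = {
            "origin": self.frame.origin.tolist(),
            "coronal_axis": self.frame.coronal_axis.tolist(),
            "sagittal_axis": self.frame.sagittal_axis.tolist(),
            "vertical_axis": self.frame.vertical_axis.tolist(),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkSet":
        frame = AnatomicalFrame(
            origin=d["frame"]["origin"],
            coronal_axis=d["frame"]["coronal_axis"],
            sagittal_axis=d["frame"]["sagittal_axis"],
            vertical_axis=d["frame"]["vertical_axis"],
        )
        return cls(frame=frame, **{name: np.asarray(d[name], float) for name in LANDMARK_NAMES})


def build_frame(mesh: trimesh.Trimesh, hint=None) -> AnatomicalFrame:
    """Anatomical frame of a mesh.

    With an explicit ``hint`` (an :class:`AnatomicalFrame` or a 3x3 array of
    row axes coronal/sagittal/vertical) the hint is returned after
    re-orthonormalization.  Without a hint the mesh principal axes are used,
    labelled by extent: vertical gets the largest extent, then medial-lateral,
    then anterior-posterior.
    """
    vertices = np.asarray(mesh.vertices, dtype=float)
    if len(vertices) < 4:
        raise FrameUndefinedError("mesh has fewer than 4 vertices")
    center = vertices.mean(axis=0)
    if hint is not None:
        if isinstance(hint, AnatomicalFrame):
            return orthonormal_frame(
                hint.origin, hint.coronal_axis, hint.sagittal_axis, hint.vertical_axis
            )
        hint = np.asarray(hint, dtype=float)
        return orthonormal_frame(center, hint[0], hint[1], hint[2] if len(hint) > 2 else None)

    centered = vertices - center
    # principal axes from the vertex covariance
    u, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[-1] < 1e-12 * max(svals[0], 1.0) and len(vertices) >= 4:
        # all vertices coplanar -> no third axis
        raise FrameUndefinedError("mesh vertices are coplanar; frame undefined")
    extents = np.array([np.ptp(centered @ ax) for ax in vt])
    order = np.argsort(extents)[::-1]  # largest extent first
    axes = vt[order]
    # canonical signs: largest-magnitude component of each axis positive
    for i in range(3):
        if axes[i][np.argmax(np.abs(axes[i]))] < 0:
            axes[i] = -axes[i]
    vertical, coronal, sagittal = axes[0], axes[1], axes[2]
    return orthonormal_frame(center, coronal, sagittal, vertical)


def _default_split_coordinate(coords_c: np.ndarray) -> float:
    """Coronal coordinate of the sagittal splitting plane.

    Heuristic for the intercondylar fossa: scan the central 70% of the
    coronal range in 32 bins and split at the emptiest bin (fewest surface
    vertices = minimum material width).
    """
    lo, hi = coords_c.min(), coords_c.max()
    span = hi - lo
    edges = np.linspace(lo + 0.15 * span, hi - 0.15 * span, 33)
    counts, _ = np.histogram(coords_c, bins=edges)
    i = int(np.argmin(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


def _region_vertex_indices(mesh: trimesh.Trimesh, frame: AnatomicalFrame, condyle_split):
    """Vertex index arrays (medial, lateral) for the two condyle regions."""
    cc = (np.asarray(mesh.vertices) - frame.origin) @ frame.coronal_axis
    if condyle_split is not None and not np.isscalar(condyle_split):
        tags = np.asarray(condyle_split)
        if len(tags) != len(mesh.faces):
            raise ValueError("per-face tags must have one entry per face")
        faces = np.asarray(mesh.faces)
        n_vert = len(mesh.vertices)
        total = np.zeros(n_vert, dtype=int)
        np.add.at(total, faces.ravel(), 1)
        out = []
        for tag in ("medial", "lateral"):
            count = np.zeros(n_vert, dtype=int)
            np.add.at(count, faces[tags == tag].ravel(), 1)
            # interior vertices only: every incident face carries the tag, so
            # crease vertices of neighbouring regions cannot leak in
            strict = np.flatnonzero((count > 0) & (count == total))
            out.append(strict if len(strict) else np.flatnonzero(count > 0))
        return out[0], out[1]
    split = _default_split_coordinate(cc) if condyle_split is None else float(condyle_split)
    idx = np.arange(len(cc))
    return idx[cc < split], idx[cc >= split]


def detect_landmarks(
    mesh: trimesh.Trimesh, frame: AnatomicalFrame, condyle_split=None
) -> LandmarkSet:
    """Detect the eight condylar extremal landmarks on a mesh.

    ``condyle_split`` may be ``None`` (default sagittal plane through the
    fossa's emptiest cross-section), a scalar coronal coordinate, or a
    per-face tag array containing ``"medial"``/``"lateral"``.
    """
    vertices = np.asarray(mesh.vertices, dtype=float)
    medial_idx, lateral_idx = _region_vertex_indices(mesh, frame, condyle_split)
    points = {}
    for prefix, idx in (("M", medial_idx), ("L", lateral_idx)):
        region = "medial" if prefix == "M" else "lateral"
        if len(idx) == 0:
            raise MissingLandmarkError(f"{region} condyle region is empty")
        local = frame.coords(vertices[idx])
        cc, vv = local[:, 0], local[:, 2]
        # np.argmin/argmax take the first occurrence: lowest vertex index wins ties
        points[f"{prefix}_medial"] = vertices[idx[np.argmin(cc)]]
        points[f"{prefix}_lateral"] = vertices[idx[np.argmax(cc)]]
        points[f"{prefix}_high"] = vertices[idx[np.argmax(vv)]]
        points[f"{prefix}_low"] = vertices[idx[np.argmin(vv)]]
    return LandmarkSet(frame=frame, **points)


def condyle_side_mesh(
    mesh: trimesh.Trimesh, frame: AnatomicalFrame, side: str, condyle_split=None
) -> trimesh.Trimesh:
    """Submesh of one condyle region (for per-side projection/segmentation).

    With per-face tags the tagged faces are taken verbatim; otherwise faces
    are assigned by the coronal coordinate of their centroid relative to the
    (given or default) sagittal split plane.
    """
    if side not in ("medial", "lateral"):
        raise ValueError(f"unknown side {side!r}")
    if condyle_split is not None and not np.isscalar(condyle_split):
        tags = np.asarray(condyle_split)
        faces = np.flatnonzero(tags == side)
    else:
        cc = (mesh.triangles_center - frame.origin) @ frame.coronal_axis
        vv = (np.asarray(mesh.vertices) - frame.origin) @ frame.coronal_axis
        split = _default_split_coordinate(vv) if condyle_split is None else float(condyle_split)
        faces = np.flatnonzero(cc < split if side == "medial" else cc >= split)
    if len(faces) == 0:
        raise MissingLandmarkError(f"{side} condyle region is empty")
    return mesh.submesh([faces], append=True)


def load_mesh(path) -> trimesh.Trimesh:
    """Load an STL/PLY/OBJ surface mesh; quads are triangulated on load."""
    mesh = trimesh.load_mesh(path)
    if isinstance(mesh, trimesh.Scene):
        mesh = trimesh.util.concatenate(list(mesh.geometry.values()))
    return mesh
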