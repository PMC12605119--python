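"""Discrete curvature combs and fairness statistics for feature curves.

Profile curvature is estimated per interior sample by the circumscribed
circle (Menger curvature) of each consecutive point triple — robust on
projected, slightly noisy polylines.  The comb direction at a sample is the
in-plane normal (toward the local circumcentre), scaled by the curvature for
display.
"""

from __future__ import annotations

import numpy as np

from .errors import DegeneratePolylineError
from .surface import FeatureCurve


def discrete_curvature(curve) -> tuple[np.ndarray, np.ndarray]:
    """Menger curvature (mm^-1) and comb normals at interior samples.

    Returns ``(curvatures, normals)`` of length ``n - 2`` for ``n`` samples;
    collinear triples get curvature 0 and a zero normal.
    """
    pts = curve.points if isinstance(curve, FeatureCurve) else np.asarray(curve, float)
    if len(pts) < 3:
        raise DegeneratePolylineError("need at least 3 samples for curvature")
    p0, p1, p2 = pts[:-2], pts[1:-1], pts[2:]
    a = np.linalg.norm(p1 - p0, axis=1)
    b = np.linalg.norm(p2 - p1, axis=1)
    c = np.linalg.norm(p2 - p0, axis=1)
    if np.any(a < 1e-12) or np.any(b < 1e-12):
        raise DegeneratePolylineError("duplicate consecutive samples")
    cross = np.cross(p1 - p0, p2 - p1)
    area2 = np.linalg.norm(cross, axis=1)  # twice the triangle area
    denom = a * b * c
    k = np.where(denom > 1e-30, 2.0 * area2 / np.maximum(denom, 1e-30), 0.0)

    # comb normal: in-plane perpendicular to the local tangent, toward the
    # circumcentre side (the bisector of the two segment directions)
    bisect = (p0 - p1) / a[:, None] + (p2 - p1) / b[:, None]
    nb = np.linalg.norm(bisect, axis=1)
    normals = np.zeros_like(bisect)
    ok = nb > 1e-12
    normals[ok] = bisect[ok] / nb[ok, None]
    return k, normals


def curvature_stats(curvatures) -> tuple[float, float]:
    """(max absolute curvature, standard deviation along the profile)."""
    k = np.abs(np.asarray(list(curvatures), dtype=float))
    if len(k) == 0:
        raise DegeneratePolylineError("empty curvature profile")
    return float(np.max(k)), float(np.std(k))
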