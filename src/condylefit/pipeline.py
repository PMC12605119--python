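"""End-to-end orchestration of the three-step attachment-surface pipeline.

Step 1 builds the four finger contour feature lines of each side from the
condylar landmarks; Step 2 lofts them into the parametric fitting surface;
Step 3 projects the contours onto the bone, segments the enclosed condylar
region and reconstructs it into the attachment surface.  Fit is quantified by
the symmetric Hausdorff distance between corresponding point samples of the
attachment surface and the underlying condylar region.

Only the condylar span of each contour (between the first and third joint
points) is projected: the start/end phalanx extensions belong to the
osteotomy planes and deliberately overhang the bone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import trimesh

from .anatomy import (
    AnatomicalFrame,
    LandmarkSet,
    build_frame,
    condyle_side_mesh,
    detect_landmarks,
)
from .contours import (
    BionicParams,
    CoefficientSet,
    compute_offsets,
    fit_feature_curve,
    place_key_points,
)
from .metrics import FitReport, hausdorff_distance, sample_points
from .projection import project_curve, reconstruct_attachment, segment_by_contours
from .surface import FittingSurface, build_fitting_surface, measure_width_params

log = logging.getLogger(__name__)


@dataclass
class SideResult:
    """Everything produced for one condyle side."""

    side: str
    curves: list
    fitting_surface: FittingSurface
    projected: list
    region: trimesh.Trimesh  # segmented condylar patch (on the bone)
    attachment: trimesh.Trimesh
    report: FitReport


@dataclass
class DesignResult:
    medial: SideResult
    lateral: SideResult
    landmarks: LandmarkSet
    report: FitReport

    @property
    def sides(self):
        return {"medial": self.medial, "lateral": self.lateral}


def build_side_curves(
    landmarks: LandmarkSet,
    coeffs: CoefficientSet,
    params: BionicParams,
    side: str,
    samples_per_segment: int = 8,
    span_convention: str = "as-published",
):
    """Step 1 for one side: the four finger feature curves."""
    rows = params.medial if side == "medial" else params.lateral
    curves = []
    for finger in (1, 2, 3, 4):
        offsets = compute_offsets(landmarks, coeffs, side, finger, span_convention)
        angles_hint = rows[finger - 1][0]
        poly = place_key_points(landmarks, offsets, side, finger, params.d0, angles_hint)
        curves.append(fit_feature_curve(poly, samples_per_segment))
    return curves


def corresponding_samples(
    region: trimesh.Trimesh,
    attachment: trimesh.Trimesh,
    density: float,
    seed: int,
):
    """Corresponding point samples of the bone region and the plate.

    When reconstruction preserved the region's triangulation (the usual case:
    no interior holes), one set of area-uniform barycentric draws on the
    region is evaluated on both meshes, and both vertex sets are included, so
    the comparison measures true surface deviation rather than sampling gaps.
    Otherwise two independent seeded samples are drawn.
    """
    if np.array_equal(region.faces, attachment.faces):
        n = max(1, int(round(density * float(region.area))))
        pts_b, face_idx, bary = trimesh.sample.sample_surface(
            region, n, seed=int(seed), return_barycentric=True
        )
        tri_a = attachment.vertices[attachment.faces[face_idx]]
        pts_a = np.einsum("nk,nkj->nj", bary, tri_a)
        a = np.vstack([pts_a, attachment.vertices])
        b = np.vstack([np.asarray(pts_b, float), region.vertices])
        return a, b
    a = sample_points(attachment, density, seed, source="plate").points
    b = sample_points(region, density, seed + 1, source="femur").points
    return a, b


def design_side(
    femur: trimesh.Trimesh,
    landmarks: LandmarkSet,
    coeffs: CoefficientSet,
    params: BionicParams,
    side: str,
    condyle_split=None,
    samples_per_segment: int = 8,
    transverse_samples: int = 6,
    smoothing_passes: int = 1,
    density: float = 10.0,
    seed: int = 0,
    span_convention: str = "as-published",
    side_mesh: trimesh.Trimesh | None = None,
    max_miss_fraction: float = 0.9,
) -> SideResult:
    """Run Steps 1-3 for one condyle side and assess the fit.

    Projection and segmentation are restricted to the side's own condylar
    region so rays cannot cross the intercondylar fossa and land on the
    opposite lobe.
    """
    curves = build_side_curves(
        landmarks, coeffs, params, side, samples_per_segment, span_convention
    )
    widths = measure_width_params(landmarks)
    fitting = build_fitting_surface(curves, widths, transverse_samples)

    if side_mesh is None:
        side_mesh = condyle_side_mesh(femur, landmarks.frame, side, condyle_split)
    sign = -1.0 if side == "medial" else 1.0
    direction = sign * landmarks.frame.coronal_axis
    # outer fingers may overhang the condylar silhouette at their offset
    # station; their samples clamp to the rim via the closest-point fallback
    projected = [
        project_curve(c.trimmed(1, 3), side_mesh, direction, max_miss_fraction=max_miss_fraction)
        for c in curves
    ]

    boundary = np.vstack([projected[0].points, projected[3].points[::-1]])
    seed_point = projected[1].points[len(projected[1]) // 2]
    region = segment_by_contours(side_mesh, boundary, seed_point)
    attachment = reconstruct_attachment(region, smoothing_passes)

    a, b = corresponding_samples(region, attachment, density, seed)
    h, d_ab, d_ba = hausdorff_distance(a, b, return_directed=True)
    report = FitReport(hausdorff=h, directed_ab=d_ab, directed_ba=d_ba, mean_distance=None)
    return SideResult(side, curves, fitting, projected, region, attachment, report)


def design_attachment(
    femur: trimesh.Trimesh,
    landmarks: LandmarkSet | None,
    coeffs: CoefficientSet,
    params: BionicParams,
    condyle_split=None,
    frame: AnatomicalFrame | None = None,
    seed: int = 0,
    **side_kwargs,
) -> DesignResult:
    """Run the full bilateral pipeline.

    ``landmarks=None`` triggers automatic frame construction and extremal
    landmark detection (``condyle_split`` may supply per-face region tags or
    a split coordinate).
    """
    if landmarks is None:
        if frame is None:
            frame = build_frame(femur)
        landmarks = detect_landmarks(femur, frame, condyle_split)
    sides = {}
    for side in ("medial", "lateral"):
        log.info("designing %s attachment surface", side)
        sides[side] = design_side(
            femur, landmarks, coeffs, params, side,
            condyle_split=condyle_split, seed=seed, **side_kwargs
        )
    h = max(sides["medial"].report.hausdorff, sides["lateral"].report.hausdorff)
    report = FitReport(
        hausdorff=h,
        directed_ab=max(s.report.directed_ab for s in sides.values()),
        directed_ba=max(s.report.directed_ba for s in sides.values()),
        mean_distance=float(
            np.mean([s.report.hausdorff for s in sides.values()])
        ),
        per_group=[sides["medial"].report.hausdorff, sides["lateral"].report.hausdorff],
    )
    return DesignResult(
        medial=sides["medial"], lateral=sides["lateral"], landmarks=landmarks, report=report
    )
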