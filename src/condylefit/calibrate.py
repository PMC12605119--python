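"""Calibration of the six offset scaling coefficients.

The coefficients translate condylar spans into finger offsets and cannot be
derived from first principles; they are calibrated against a cohort of cases
by derivative-free minimization of the mean Hausdorff distance between the
attachment-surface feature points generated from candidate coefficients and
each case's native condylar reference set.  The Nelder-Mead simplex method is
used, bounded to (0.1, 2.0) per coefficient.

A case carries its own reference point set (feature points of the target
attachment region).  For synthetic cohorts the reference is generated by
running the pipeline with known ("planted") coefficients, which makes the
calibration a parameter-recovery problem with known ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.optimize import minimize

from .anatomy import LandmarkSet, condyle_side_mesh, detect_landmarks
from .contours import BionicParams, CoefficientSet
from .errors import CondylefitError, InvalidParameterError
from .metrics import hausdorff_distance
from .pipeline import design_side
from .synthetic import generate_cohort

log = logging.getLogger(__name__)

BOUNDS = (0.1, 2.0)


@dataclass
class CalibrationCase:
    """One cohort member: bone mesh, landmarks and reference feature points."""

    mesh: trimesh.Trimesh
    landmarks: LandmarkSet
    reference_points: dict  # side -> list of per-finger (n, 3) feature point arrays
    name: str = ""
    condyle_split: object = None
    # cached per-side submeshes (projection targets); built lazily
    _side_meshes: dict = field(default_factory=dict, repr=False)

    def side_mesh(self, side: str) -> trimesh.Trimesh:
        if side not in self._side_meshes:
            self._side_meshes[side] = condyle_side_mesh(
                self.mesh, self.landmarks.frame, side, self.condyle_split
            )
        return self._side_meshes[side]


def attachment_feature_points(
    mesh: trimesh.Trimesh,
    landmarks: LandmarkSet,
    coeffs: CoefficientSet,
    params: BionicParams,
    condyle_split=None,
    side_meshes: dict | None = None,
    sides=("medial", "lateral"),
    **side_kwargs,
) -> dict[str, np.ndarray]:
    """Per-side feature point sets of the bilateral attachment design.

    Runs the full per-side pipeline (contours, loft, projection, segmentation,
    reconstruction; infeasible designs raise) and collects the projected
    contour feature-line samples of the four fingers of each side.  Unlike the
    segmented region's vertex set, these points move continuously with the
    coefficients, which makes them a well-behaved calibration currency.  The
    sets are kept separate per side and per finger: each attachment surface
    is its own fit problem (medial depends only on the deltas, lateral only
    on the epsilons), and pooling the fingers into one set would let a finger
    alias onto a neighbouring finger's reference line, which creates spurious
    optima at rational offset ratios.
    """
    pts = {}
    for side in sides:
        res = design_side(
            mesh,
            landmarks,
            coeffs,
            params,
            side,
            condyle_split=condyle_split,
            side_mesh=None if side_meshes is None else side_meshes.get(side),
            **side_kwargs,
        )
        pts[side] = [np.asarray(p.points, float) for p in res.projected]
    return pts


def objective(
    coeffs: CoefficientSet,
    cases: list[CalibrationCase],
    params: BionicParams,
    sides=("medial", "lateral"),
    **side_kwargs,
) -> float:
    """Mean Hausdorff distance (mm) of candidate designs over a cohort.

    Each case contributes the Hausdorff distance of every projected contour
    feature line (four fingers per side) to the corresponding reference
    feature line; the objective is the mean over all case-side-finger
    triples.  Cases on which the pipeline fails are skipped with a warning;
    if every case fails the candidate is infeasible and an error is raised.
    """
    if len(cases) == 0:
        raise InvalidParameterError("at least one calibration case required")
    # a candidate whose contours overhang the silhouette entirely is a bad
    # design, not an evaluation failure: let every sample clamp to the rim so
    # the objective stays finite (no penalty walls inside the search box)
    side_kwargs.setdefault("max_miss_fraction", 1.0)
    values = []
    for case in cases:
        try:
            pts = attachment_feature_points(
                case.mesh,
                case.landmarks,
                coeffs,
                params,
                condyle_split=case.condyle_split,
                side_meshes={s: case.side_mesh(s) for s in sides},
                sides=sides,
                **side_kwargs,
            )
            for side in sides:
                for cand, ref in zip(pts[side], case.reference_points[side]):
                    values.append(hausdorff_distance(cand, ref))
        except CondylefitError as exc:
            log.warning("calibration case %s skipped: %s", case.name, exc)
    if not values:
        raise CondylefitError("pipeline failed on every calibration case")
    return float(np.mean(values))


@dataclass
class CalibrationResult:
    coefficients: CoefficientSet
    objective: float
    converged: bool
    n_evaluations: int
    trace: list  # (evaluation, best objective so far, coefficients)


def calibrate_coefficients(
    cases: list[CalibrationCase],
    params: BionicParams,
    init: CoefficientSet | None = None,
    tol: float = 1e-3,
    max_iter: int = 400,
    seed: int = 0,
    **side_kwargs,
) -> CalibrationResult:
    """Nelder-Mead calibration of the six coefficients over a cohort.

    Starts at ``init`` (all 1.0 by default) with simplex step 0.15 per
    coefficient, bounded to (0.1, 2.0).  The objective separates additively
    by side -- the deltas only enter through the medial contours, the
    epsilons through the lateral ones -- so the six-dimensional problem is
    solved as two independent three-dimensional simplex minimizations (same
    minimizer, better conditioned).  Because each per-side objective is a
    mean of feature-point maxima (piecewise linear, not smooth), each block
    is additionally restarted from its best point with successively smaller
    initial steps (0.15, 0.05, 0.02), the standard remedy for Nelder-Mead on
    minimax-type landscapes.  ``tol`` is the simplex function tolerance in mm
    (the objective resolution is bounded by mesh granularity, so tighter
    tolerances buy nothing).  Returns the best coefficients and a monotone
    best-objective trace; ``converged`` is False if the evaluation budget ran
    out first.
    """
    x0 = np.clip(np.ones(6) if init is None else init.as_array(), *BOUNDS)
    trace: list = []
    state = {"n": 0, "x": x0.copy(), "block_best": {}}
    blocks = {"medial": slice(0, 3), "lateral": slice(3, 6)}

    def combined_best() -> float:
        vals = [v for v in state["block_best"].values() if np.isfinite(v)]
        return float(np.mean(vals)) if vals else np.inf

    # baseline both sides at the start so the combined best-objective trace is
    # well-defined (and monotone) from the first evaluation on
    for side in blocks:
        try:
            state["block_best"][side] = objective(
                CoefficientSet.from_array(x0), cases, params, sides=(side,), **side_kwargs
            )
        except CondylefitError:
            state["block_best"][side] = 1e3
        state["n"] += 1
    trace.append((state["n"], combined_best(), tuple(x0)))

    converged = True
    for side, sl in blocks.items():
        best = {"val": state["block_best"][side], "x": x0[sl].copy()}

        def f(x3, side=side, sl=sl, best=best):
            full = state["x"].copy()
            full[sl] = np.clip(x3, *BOUNDS)
            try:
                val = objective(
                    CoefficientSet.from_array(full), cases, params, sides=(side,), **side_kwargs
                )
            except CondylefitError:
                # geometrically infeasible candidate (contours off the bone)
                val = 1e3
            state["n"] += 1
            if val < best["val"]:
                best["val"] = val
                best["x"] = np.clip(np.asarray(x3, float), *BOUNDS)
            state["block_best"][side] = best["val"]
            trace.append((state["n"], combined_best(), tuple(np.clip(full, *BOUNDS))))
            return val

        block_converged = False
        block_start = state["n"]
        for step in (0.15, 0.05, 0.02):
            budget = max_iter // 2 - (state["n"] - block_start)
            if budget <= 10:
                break
            xs = best["x"]
            simplex = np.vstack(
                [xs] + [np.clip(xs + step * np.eye(3)[i], *BOUNDS) for i in range(3)]
            )
            res = minimize(
                f,
                xs,
                method="Nelder-Mead",
                bounds=[BOUNDS] * 3,
                options={
                    "xatol": 1e-3,
                    "fatol": tol,
                    "maxiter": budget,
                    "initial_simplex": simplex,
                    "adaptive": True,
                },
            )
            block_converged = bool(res.success)
            if best["val"] <= tol:
                break
        state["x"][sl] = best["x"]
        converged = converged and block_converged

    final = CoefficientSet.from_array(state["x"])
    return CalibrationResult(
        coefficients=final,
        objective=combined_best(),
        converged=converged,
        n_evaluations=state["n"],
        trace=trace,
    )


def make_calibration_cohort(
    n: int = 5,
    planted: CoefficientSet | None = None,
    params: BionicParams | None = None,
    variation: float = 0.1,
    edge_length: float = 3.0,
    seed: int = 0,
    **side_kwargs,
) -> tuple[list[CalibrationCase], CoefficientSet]:
    """Synthetic cohort whose reference feature points use planted coefficients.

    Returns ``(cases, planted)``; calibrating the cases from a neutral start
    should recover the planted coefficients (parameter-recovery experiment).
    """
    from .contours import design_group_params

    planted = CoefficientSet() if planted is None else planted
    params = design_group_params(1) if params is None else params
    cases = []
    for k, (mesh, _) in enumerate(generate_cohort(n, variation, edge_length, seed)):
        tags = mesh.metadata["face_region"]
        landmarks = detect_landmarks(mesh, mesh.metadata["shape"].frame(), tags)
        ref = attachment_feature_points(
            mesh, landmarks, planted, params, condyle_split=tags, **side_kwargs
        )
        cases.append(
            CalibrationCase(
                mesh=mesh,
                landmarks=landmarks,
                reference_points=ref,
                name=f"case{k}",
                condyle_split=tags,
            )
        )
    return cases, planted
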