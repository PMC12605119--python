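"""File formats: JSON parameters/landmarks/coefficients/reports, CSV curves.

All coordinates are mm and all angles degrees at the file boundary.  The
parameter file mirrors the design-table schema: per-side bending angles
(``alpha``/``beta``), segment lengths (``M``/``L``), widths (``Wm``/``Wl``),
the osteotomy offset ``d0`` and the offset coefficients
(``delta``/``epsilon``).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .anatomy import LandmarkSet
from .contours import BendingAngles, BionicParams, CoefficientSet, SegmentLengths
from .metrics import FitReport
from .surface import FeatureCurve


# ---- landmarks -------------------------------------------------------------


def save_landmarks(path, landmarks: LandmarkSet) -> None:
    Path(path).write_text(json.dumps(landmarks.to_dict(), indent=2))


def load_landmarks(path) -> LandmarkSet:
    return LandmarkSet.from_dict(json.loads(Path(path).read_text()))


# ---- parameters ------------------------------------------------------------


def params_to_dict(params: BionicParams, coeffs: CoefficientSet | None = None) -> dict:
    ma, ml = params.medial[0]
    la, ll = params.lateral[0]
    d = {
        "alpha": list(ma.as_tuple()),
        "beta": list(la.as_tuple()),
        "M": list(ml.as_tuple()),
        "L": list(ll.as_tuple()),
        "d0": params.d0,
    }
    if params.widths is not None:
        d["Wm"] = params.widths.W_m
        d["Wl"] = params.widths.W_l
    if coeffs is not None:
        d["delta"] = [coeffs.delta1, coeffs.delta2, coeffs.delta3]
        d["epsilon"] = [coeffs.epsilon1, coeffs.epsilon2, coeffs.epsilon3]
    return d


def params_from_dict(d: dict) -> tuple[BionicParams, CoefficientSet]:
    medial = (BendingAngles(*d["alpha"]), SegmentLengths(*d["M"]))
    lateral = (BendingAngles(*d["beta"]), SegmentLengths(*d["L"]))
    params = BionicParams.from_rows(medial, lateral, d0=float(d.get("d0", 5.0)))
    delta = d.get("delta", [0.76] * 3)
    epsilon = d.get("epsilon", [0.76] * 3)
    coeffs = CoefficientSet(*delta, *epsilon)
    return params, coeffs


def save_params(path, params: BionicParams, coeffs: CoefficientSet | None = None) -> None:
    Path(path).write_text(json.dumps(params_to_dict(params, coeffs), indent=2))


def load_params(path) -> tuple[BionicParams, CoefficientSet]:
    return params_from_dict(json.loads(Path(path).read_text()))


# ---- coefficients ----------------------------------------------------------


def save_coefficients(path, coeffs: CoefficientSet) -> None:
    d = {
        "delta": [coeffs.delta1, coeffs.delta2, coeffs.delta3],
        "epsilon": [coeffs.epsilon1, coeffs.epsilon2, coeffs.epsilon3],
    }
    Path(path).write_text(json.dumps(d, indent=2))


def load_coefficients(path) -> CoefficientSet:
    d = json.loads(Path(path).read_text())
    return CoefficientSet(*d["delta"], *d["epsilon"])


# ---- curves ----------------------------------------------------------------


def save_curve_csv(path, curve: FeatureCurve) -> None:
    """Ordered-point CSV (x,y,z mm) with key points and fallback flags marked."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x_mm", "y_mm", "z_mm", "is_key_point", "projection_fallback"])
        knots = set(int(k) for k in curve.knots)
        for i, p in enumerate(curve.points):
            flag = int(bool(curve.flags[i])) if curve.flags is not None else 0
            writer.writerow(
                [f"{p[0]:.6f}", f"{p[1]:.6f}", f"{p[2]:.6f}", int(i in knots), flag]
            )


def load_curve_csv(path, side: str = "medial", finger_index: int = 1) -> FeatureCurve:
    rows = list(csv.DictReader(open(path)))
    pts = np.array([[float(r["x_mm"]), float(r["y_mm"]), float(r["z_mm"])] for r in rows])
    knots = np.array([i for i, r in enumerate(rows) if int(r["is_key_point"])], dtype=int)
    flags = np.array([bool(int(r.get("projection_fallback", 0))) for r in rows])
    return FeatureCurve(side, finger_index, pts, knots, flags=flags)


def save_comb_csv(path, arclengths, curvatures, normals) -> None:
    """Curvature comb CSV: arclength, curvature and comb normal per sample."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["arclength_mm", "curvature_per_mm", "nx", "ny", "nz"])
        for s, k, n in zip(arclengths, curvatures, normals):
            writer.writerow([f"{s:.6f}", f"{k:.8f}", f"{n[0]:.6f}", f"{n[1]:.6f}", f"{n[2]:.6f}"])


def save_trace_csv(path, trace) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["evaluation", "best_objective_mm", "delta1", "delta2", "delta3",
             "epsilon1", "epsilon2", "epsilon3"]
        )
        for n, best, x in trace:
            writer.writerow([n, f"{best:.6f}"] + [f"{v:.6f}" for v in x])


# ---- reports ---------------------------------------------------------------


def save_report(path, report: FitReport, extra: dict | None = None) -> None:
    d = report.to_dict()
    if extra:
        d.update(extra)
    Path(path).write_text(json.dumps(d, indent=2))
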