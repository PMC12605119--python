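"""Finger contour construction, bending/length parameterization, inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from condylefit.contours import (
    DESIGN_GROUPS,
    BendingAngles,
    CoefficientSet,
    FingerPolyline,
    SegmentLengths,
    compute_bending_angles,
    compute_offsets,
    compute_segment_lengths,
    fit_feature_curve,
    forward_construct,
    place_key_points,
)
from condylefit.errors import (
    DegeneratePolylineError,
    InvalidParameterError,
    OutOfRangeAngleError,
)

from conftest import random_rotation


class TestOffsets:
    def test_index_finger_offsets_are_zero(self, simple_landmarks):
        off = compute_offsets(simple_landmarks, CoefficientSet(), "medial", 1)
        assert off.as_array().tolist() == [0.0, 0.0, 0.0]

    def test_second_finger_level1_uses_medial_span(self, simple_landmarks):
        # medial span 30 mm, delta1 0.76: h1 = 1 * 10 * 0.76
        off = compute_offsets(simple_landmarks, CoefficientSet(), "medial", 2)
        assert off.h1 == pytest.approx(7.6)
        # levels 2-3 use the lateral span (20 mm) in the published convention
        assert off.h2 == pytest.approx(20.0 / 3.0 * 0.76)

    def test_fourth_finger_level1(self, simple_landmarks):
        off = compute_offsets(simple_landmarks, CoefficientSet(), "medial", 4)
        assert off.h1 == pytest.approx(22.8)

    def test_same_side_convention_uses_medial_span_throughout(self, simple_landmarks):
        off = compute_offsets(
            simple_landmarks, CoefficientSet(), "medial", 3, span_convention="same-side"
        )
        assert off.h2 == pytest.approx(2 * 10.0 * 0.76)
        assert off.h2 == off.h3 == pytest.approx(off.h1)

    @settings(max_examples=30, derandomize=True)
    @given(
        scale=st.floats(0.1, 10.0),
        coeff=st.floats(0.1, 2.0),
        finger=st.integers(2, 4),
    )
    def test_offsets_homogeneous_in_span_and_linear_in_coefficients(
        self, scale, coeff, finger
    ):
        from conftest import make_grid_mesh  # noqa: F401  (fixture module import)
        from condylefit.anatomy import AnatomicalFrame, LandmarkSet

        frame = AnatomicalFrame(np.zeros(3), [1, 0, 0], [0, 1, 0], [0, 0, 1])

        def landmarks(s):
            return LandmarkSet(
                M_medial=[0, 0, 0], M_lateral=[30 * s, 0, 0],
                M_high=[15 * s, 0, 18 * s], M_low=[15 * s, 0, -18 * s],
                L_medial=[50 * s, 0, 0], L_lateral=[50 * s + 20 * s, 0, 0],
                L_high=[60 * s, 0, 16 * s], L_low=[60 * s, 0, -16 * s],
                frame=frame,
            )

        base = compute_offsets(landmarks(1.0), CoefficientSet(), "medial", finger)
        scaled = compute_offsets(landmarks(scale), CoefficientSet(), "medial", finger)
        assert np.allclose(scaled.as_array(), scale * base.as_array(), rtol=1e-9)

        c = CoefficientSet(coeff, coeff, coeff, coeff, coeff, coeff)
        mult = compute_offsets(landmarks(1.0), c, "medial", finger)
        assert np.allclose(mult.as_array(), coeff / 0.76 * base.as_array(), rtol=1e-9)

    def test_degenerate_span_raises(self, canonical_frame):
        from condylefit.anatomy import LandmarkSet
        from condylefit.errors import DegenerateLandmarksError

        lms = LandmarkSet(
            M_medial=[0, 0, 0], M_lateral=[0, 0, 0], M_high=[0, 0, 5], M_low=[0, 0, -5],
            L_medial=[10, 0, 0], L_lateral=[30, 0, 0], L_high=[20, 0, 5], L_low=[20, 0, -5],
            frame=canonical_frame,
        )
        with pytest.raises(DegenerateLandmarksError):
            compute_offsets(lms, CoefficientSet(), "medial", 2)


class TestPlaceKeyPoints:
    def test_index_finger_joints_sit_at_landmarks(self, simple_landmarks):
        off = compute_offsets(simple_landmarks, CoefficientSet(), "medial", 1)
        poly = place_key_points(simple_landmarks, off, "medial", 1, d0=5.0)
        assert np.allclose(poly.k1, simple_landmarks.M_high)
        assert np.allclose(poly.k2, simple_landmarks.M_medial)
        assert np.allclose(poly.k3, simple_landmarks.M_low)

    def test_joint_heights_match_landmark_heights(self, simple_landmarks):
        off = compute_offsets(simple_landmarks, CoefficientSet(), "lateral", 3)
        poly = place_key_points(simple_landmarks, off, "lateral", 3, d0=5.0)
        f = simple_landmarks.frame
        assert poly.k1 @ f.vertical_axis == pytest.approx(
            simple_landmarks.L_high @ f.vertical_axis, abs=1e-9
        )
        assert poly.k3 @ f.vertical_axis == pytest.approx(
            simple_landmarks.L_low @ f.vertical_axis, abs=1e-9
        )

    def test_doubling_offsets_doubles_displacement(self, simple_landmarks):
        from condylefit.contours import OffsetTriple

        off1 = OffsetTriple(2.0, 3.0, 4.0)
        off2 = OffsetTriple(4.0, 6.0, 8.0)
        p1 = place_key_points(simple_landmarks, off1, "medial", 2, d0=5.0)
        p2 = place_key_points(simple_landmarks, off2, "medial", 2, d0=5.0)
        d1 = p1.k2 - simple_landmarks.M_medial
        d2 = p2.k2 - simple_landmarks.M_medial
        assert np.allclose(d2, 2 * d1, atol=1e-12)

    def test_offset_directions_oppose_across_sides(self, simple_landmarks):
        from condylefit.contours import OffsetTriple

        off = OffsetTriple(0.0, 5.0, 0.0)
        med = place_key_points(simple_landmarks, off, "medial", 2, d0=5.0)
        lat = place_key_points(simple_landmarks, off, "lateral", 2, d0=5.0)
        sag = simple_landmarks.frame.sagittal_axis
        assert (med.k2 - simple_landmarks.M_medial) @ sag == pytest.approx(-5.0)
        assert (lat.k2 - simple_landmarks.L_lateral) @ sag == pytest.approx(5.0)

    def test_nonpositive_d0_raises(self, simple_landmarks):
        off = compute_offsets(simple_landmarks, CoefficientSet(), "medial", 1)
        with pytest.raises(InvalidParameterError):
            place_key_points(simple_landmarks, off, "medial", 1, d0=0.0)

    def test_end_points_satisfy_osteotomy_distance(self, simple_landmarks):
        """Perpendicular distance from start to the k1->k2 line equals d0."""
        off = compute_offsets(simple_landmarks, CoefficientSet(), "medial", 2)
        d0 = 5.0
        poly = place_key_points(simple_landmarks, off, "medial", 2, d0=d0)
        u = (poly.k2 - poly.k1) / np.linalg.norm(poly.k2 - poly.k1)
        v = poly.start - poly.k1
        perp = v - (v @ u) * u
        assert np.linalg.norm(perp) == pytest.approx(d0, abs=1e-9)

    def test_rigid_motion_equivariance(self, simple_landmarks):
        rng = np.random.default_rng(5)
        rot = random_rotation(rng)
        t = np.array([3.0, -4.0, 7.0])
        off = compute_offsets(simple_landmarks, CoefficientSet(), "medial", 3)
        base = place_key_points(simple_landmarks, off, "medial", 3, d0=5.0)
        moved_lms = simple_landmarks.transformed(rot, t)
        moved = place_key_points(moved_lms, off, "medial", 3, d0=5.0)
        assert np.allclose(moved.points, base.transformed(rot, t).points, atol=1e-9)


class TestAnglesAndLengths:
    def test_collinear_chain_has_straight_angles(self):
        poly = FingerPolyline(
            "medial", 1, [0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0], [4, 0, 0]
        )
        a = compute_bending_angles(poly)
        assert a.as_tuple() == pytest.approx((180.0, 180.0, 180.0))

    def test_right_angle_turn(self):
        poly = FingerPolyline(
            "medial", 1, [0, 0, 0], [1, 0, 0], [1, 1, 0], [1, 2, 0], [1, 3, 0]
        )
        a = compute_bending_angles(poly)
        assert a.a1 == pytest.approx(90.0)

    def test_zero_length_segment_raises(self):
        with pytest.raises(DegeneratePolylineError):
            FingerPolyline("medial", 1, [0, 0, 0], [0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0])

    def test_345_triangle_middle_length(self):
        poly = FingerPolyline(
            "medial", 1, [-1, 0, 0], [0, 0, 0], [0, 3, 4], [0, 6, 8], [0, 7, 8]
        )
        lengths = compute_segment_lengths(poly)
        assert lengths.m2 == pytest.approx(5.0)

    def test_end_length_equals_d0_at_right_angle(self):
        angles = BendingAngles(90.0, 120.0, 90.0)
        poly = forward_construct(angles, SegmentLengths(5.0, 10.0, 10.0, 5.0))
        lengths = compute_segment_lengths(poly, d0=5.0, angles=angles)
        assert lengths.m1 == pytest.approx(5.0)
        assert lengths.m4 == pytest.approx(5.0)

    def test_end_length_doubles_at_150_degrees(self):
        angles = BendingAngles(150.0, 120.0, 150.0)
        poly = forward_construct(angles, SegmentLengths(10.0, 10.0, 10.0, 10.0))
        lengths = compute_segment_lengths(poly, d0=5.0, angles=angles)
        assert lengths.m1 == pytest.approx(10.0)

    def test_unbounded_end_length_raises(self):
        angles = BendingAngles(180.0, 120.0, 150.0)
        poly = forward_construct(angles, SegmentLengths(10.0, 10.0, 10.0, 10.0))
        with pytest.raises(OutOfRangeAngleError):
            compute_segment_lengths(poly, d0=5.0, angles=angles)


class TestForwardConstruct:
    def test_straight_chain(self):
        poly = forward_construct(
            BendingAngles(180.0, 180.0, 180.0), SegmentLengths(1.0, 1.0, 1.0, 1.0)
        )
        assert np.linalg.norm(poly.end - poly.start) == pytest.approx(4.0)

    def test_chain_is_planar(self):
        poly = forward_construct(
            BendingAngles(140.0, 120.0, 150.0),
            SegmentLengths(10.0, 30.0, 25.0, 9.0),
            plane_normal=(0.0, 1.0, 1.0),
        )
        n = np.array([0.0, 1.0, 1.0]) / np.sqrt(2)
        spread = (poly.points - poly.points[0]) @ n
        assert np.abs(spread).max() < 1e-9

    @settings(max_examples=50, derandomize=True)
    @given(
        a1=st.floats(10.0, 179.0),
        a2=st.floats(10.0, 179.0),
        a3=st.floats(10.0, 179.0),
        m=st.tuples(*[st.floats(0.5, 40.0)] * 4),
    )
    def test_round_trip_identity(self, a1, a2, a3, m):
        """Recomputing angles/lengths from a constructed chain reproduces them."""
        angles = BendingAngles(a1, a2, a3)
        lengths = SegmentLengths(*m)
        poly = forward_construct(angles, lengths)
        back_a = compute_bending_angles(poly)
        back_l = compute_segment_lengths(poly)
        assert np.allclose(back_a.as_tuple(), angles.as_tuple(), atol=1e-6)
        assert np.allclose(back_l.as_tuple(), lengths.as_tuple(), atol=1e-6)

    @pytest.mark.parametrize("group", [1, 2, 3, 4])
    @pytest.mark.parametrize("side", ["medial", "lateral"])
    def test_design_group_rows_round_trip(self, group, side):
        angles, lengths = DESIGN_GROUPS[group][side]
        poly = forward_construct(angles, lengths)
        back = compute_bending_angles(poly)
        assert np.allclose(back.as_tuple(), angles.as_tuple(), atol=0.01)
        back_l = compute_segment_lengths(poly)
        assert np.allclose(back_l.as_tuple(), lengths.as_tuple(), atol=0.01)


class TestFeatureCurve:
    def test_collinear_key_points_give_straight_curve(self):
        poly = FingerPolyline(
            "medial", 1, [0, 0, 0], [1, 0, 0], [2.5, 0, 0], [3, 0, 0], [4, 0, 0]
        )
        curve = fit_feature_curve(poly, samples_per_segment=5)
        assert np.abs(curve.points[:, 1:]).max() < 1e-9
        assert np.all(np.diff(curve.points[:, 0]) > 0)

    def test_curve_passes_through_key_points_exactly(self):
        poly = forward_construct(
            BendingAngles(140.0, 120.0, 150.0), SegmentLengths(10.0, 30.0, 25.0, 9.0)
        )
        curve = fit_feature_curve(poly, samples_per_segment=7)
        assert np.array_equal(curve.key_points, poly.points)

    def test_five_points_on_circle_stay_near_circle(self):
        r = 20.0
        theta = np.linspace(0.0, np.pi, 5)
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), np.zeros(5)])
        poly = FingerPolyline("medial", 1, *pts)
        curve = fit_feature_curve(poly, samples_per_segment=20)
        radii = np.linalg.norm(curve.points[:, :2], axis=1)
        assert np.abs(radii - r).max() < 0.01 * r

    def test_too_few_samples_raises(self):
        poly = forward_construct(
            BendingAngles(140.0, 120.0, 150.0), SegmentLengths(10.0, 30.0, 25.0, 9.0)
        )
        with pytest.raises(InvalidParameterError):
            fit_feature_curve(poly, samples_per_segment=1)
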