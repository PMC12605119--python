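"""Anatomical frame construction and extremal landmark detection."""

import numpy as np
import pytest
import trimesh

from condylefit.anatomy import (
    LANDMARK_NAMES,
    AnatomicalFrame,
    LandmarkSet,
    build_frame,
    condyle_side_mesh,
    detect_landmarks,
    orthonormal_frame,
)
from condylefit.errors import FrameUndefinedError, MissingLandmarkError

from conftest import random_rotation


def _box(extents=(10.0, 30.0, 50.0)):
    return trimesh.creation.box(extents=extents)


class TestBuildFrame:
    def test_axis_aligned_box_recovers_coordinate_axes(self):
        frame = build_frame(_box())
        # extents 50 > 30 > 10: vertical=z, coronal=y, sagittal=x (up to sign)
        assert abs(abs(frame.vertical_axis @ [0, 0, 1]) - 1) < 1e-9
        assert abs(abs(frame.coronal_axis @ [0, 1, 0]) - 1) < 1e-9
        assert abs(abs(frame.sagittal_axis @ [1, 0, 0]) - 1) < 1e-9

    def test_frame_is_right_handed_orthonormal(self):
        frame = build_frame(_box())
        axes = frame.axes
        assert np.allclose(axes @ axes.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(axes) == pytest.approx(1.0, abs=1e-9)

    def test_rotated_box_recovers_applied_rotation(self):
        rng = np.random.default_rng(7)
        rot = random_rotation(rng)
        box = _box()
        ref = build_frame(box)
        box.apply_transform(
            np.vstack([np.column_stack([rot, np.zeros(3)]), [0, 0, 0, 1]])
        )
        frame = build_frame(box)
        for ax in ("coronal_axis", "sagittal_axis", "vertical_axis"):
            expected = rot @ getattr(ref, ax)
            assert abs(abs(getattr(frame, ax) @ expected) - 1) < 1e-6

    def test_explicit_hint_passes_through_reorthonormalized(self):
        hint = np.array([[1.0, 1e-4, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        frame = build_frame(_box(), hint=hint)
        assert np.allclose(frame.axes @ frame.axes.T, np.eye(3), atol=1e-12)
        assert frame.coronal_axis @ [1, 0, 0] > 0.999

    def test_too_few_vertices_raises(self):
        mesh = trimesh.Trimesh(
            vertices=np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]),
            faces=np.array([[0, 1, 2]]),
            process=False,
        )
        with pytest.raises(FrameUndefinedError):
            build_frame(mesh)

    def test_coplanar_vertices_raise(self):
        from conftest import make_grid_mesh

        with pytest.raises(FrameUndefinedError):
            build_frame(make_grid_mesh(3))

    def test_parallel_hint_axes_raise(self):
        with pytest.raises(FrameUndefinedError):
            orthonormal_frame(np.zeros(3), [1, 0, 0], [1, 1e-12, 0])


class TestDetectLandmarks:
    def test_matches_exhaustive_vertex_scan(self, fine_fixture):
        """Detection equals a brute-force scan over each region's vertices."""
        mesh, analytic = fine_fixture
        tags = mesh.metadata["face_region"]
        frame = analytic.frame
        detected = detect_landmarks(mesh, frame, tags)

        faces = np.asarray(mesh.faces)
        n_vert = len(mesh.vertices)
        total = np.zeros(n_vert, int)
        np.add.at(total, faces.ravel(), 1)
        for prefix, tag in (("M", "medial"), ("L", "lateral")):
            count = np.zeros(n_vert, int)
            np.add.at(count, faces[tags == tag].ravel(), 1)
            idx = np.flatnonzero((count > 0) & (count == total))
            local = frame.coords(mesh.vertices[idx])
            oracle = {
                f"{prefix}_medial": idx[np.argmin(local[:, 0])],
                f"{prefix}_lateral": idx[np.argmax(local[:, 0])],
                f"{prefix}_high": idx[np.argmax(local[:, 2])],
                f"{prefix}_low": idx[np.argmin(local[:, 2])],
            }
            for name, vid in oracle.items():
                assert np.array_equal(detected.point(name), mesh.vertices[vid]), name

    def test_translation_equivariance_is_exact(self, coarse_fixture):
        mesh, analytic = coarse_fixture
        tags = mesh.metadata["face_region"]
        base = detect_landmarks(mesh, analytic.frame, tags)
        shifted = mesh.copy()
        shifted.apply_translation([10.0, 0.0, 0.0])
        frame2 = analytic.frame.transformed(np.eye(3), np.array([10.0, 0.0, 0.0]))
        moved = detect_landmarks(shifted, frame2, tags)
        for name in LANDMARK_NAMES:
            assert np.allclose(
                moved.point(name) - base.point(name), [10.0, 0.0, 0.0], atol=1e-12
            )

    def test_rigid_motion_equivariance(self, coarse_fixture):
        mesh, analytic = coarse_fixture
        tags = mesh.metadata["face_region"]
        base = detect_landmarks(mesh, analytic.frame, tags)
        rng = np.random.default_rng(3)
        rot = random_rotation(rng)
        t = np.array([5.0, -2.0, 1.0])
        moved_mesh = mesh.copy()
        moved_mesh.apply_transform(
            np.vstack([np.column_stack([rot, t]), [0, 0, 0, 1]])
        )
        frame2 = analytic.frame.transformed(rot, t)
        moved = detect_landmarks(moved_mesh, frame2, tags)
        expected = base.transformed(rot, t)
        # near-tied extrema may resolve to a different vertex after rotation;
        # the extremal coordinate itself is the equivariant quantity
        axes = {"medial": 0, "lateral": 0, "high": 2, "low": 2}
        for name in LANDMARK_NAMES:
            level = name.split("_")[1]
            k = axes[level]
            got = frame2.coords(moved.point(name))[0, k]
            want = frame2.coords(expected.point(name))[0, k]
            assert got == pytest.approx(want, abs=1e-6), name

    def test_sphere_highest_landmark_is_north_pole(self):
        """A lone convex lobe's high landmark is its top vertex."""
        sphere = trimesh.creation.icosphere(subdivisions=2, radius=10.0)
        sphere.apply_translation([-15.0, 0.0, 0.0])
        other = trimesh.creation.icosphere(subdivisions=1, radius=5.0)
        other.apply_translation([15.0, 0.0, 0.0])
        mesh = trimesh.util.concatenate([sphere, other])
        frame = AnatomicalFrame(np.zeros(3), [1, 0, 0], [0, 1, 0], [0, 0, 1])
        lms = detect_landmarks(mesh, frame, condyle_split=0.0)
        top = mesh.vertices[np.argmax(mesh.vertices[:, 2])]
        assert np.allclose(lms.M_high, top)
        assert lms.M_high[2] == pytest.approx(10.0, abs=1e-6)

    def test_refinement_moves_landmarks_less_than_coarse_edge(
        self, fine_landmarks, coarse_landmarks
    ):
        for name in LANDMARK_NAMES:
            d = np.linalg.norm(fine_landmarks.point(name) - coarse_landmarks.point(name))
            assert d < 8.0, name

    def test_agreement_with_analytic_landmarks(self, fine_fixture, fine_landmarks):
        _, analytic = fine_fixture
        for name in LANDMARK_NAMES:
            d = np.linalg.norm(fine_landmarks.point(name) - analytic.point(name))
            assert d < 3.0, name

    def test_empty_region_raises_named_error(self, coarse_fixture):
        mesh, analytic = coarse_fixture
        tags = np.full(len(mesh.faces), "medial")
        with pytest.raises(MissingLandmarkError, match="lateral"):
            detect_landmarks(mesh, analytic.frame, tags)


class TestSideMesh:
    def test_tagged_submesh_has_only_tagged_area(self, coarse_fixture):
        mesh, analytic = coarse_fixture
        tags = mesh.metadata["face_region"]
        sub = condyle_side_mesh(mesh, analytic.frame, "medial", tags)
        assert len(sub.faces) == int((tags == "medial").sum())

    def test_plane_split_covers_mesh(self, coarse_fixture):
        mesh, analytic = coarse_fixture
        med = condyle_side_mesh(mesh, analytic.frame, "medial")
        lat = condyle_side_mesh(mesh, analytic.frame, "lateral")
        assert len(med.faces) + len(lat.faces) == len(mesh.faces)


class TestLandmarkSerialization:
    def test_json_round_trip(self, simple_landmarks):
        d = simple_landmarks.to_dict()
        back = LandmarkSet.from_dict(d)
        for name in LANDMARK_NAMES:
            assert np.allclose(back.point(name), simple_landmarks.point(name))
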