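"""Reference-frame and cutting-plane construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from mandiseg.geometry import (
    DegenerateGeometryError,
    LandmarkSet,
    Plane,
    bisecting_plane,
    build_mandibular_planes,
    build_reference_frame,
    midsagittal_plane,
    plane_through_point_parallel_to,
    plane_through_three_points,
    plane_through_two_points_normal_to,
)
from .conftest import random_rigid_transform


def angle_between_planes(p1: Plane, p2: Plane) -> float:
    c = abs(float(p1.normal @ p2.normal))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


class TestMidsagittalPlane:
    def test_coplanar_construction(self):
        pl = midsagittal_plane((0, 0, 0), (100, 0, 0), (-30, -40, 0))
        for p in [(0, 0, 0), (100, 0, 0), (-30, -40, 0)]:
            assert abs(pl.signed_distance(np.asarray(p, float))) == 0.0
        assert np.allclose(np.abs(pl.normal), [0, 0, 1])

    def test_collinear_inputs_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            midsagittal_plane((0, 0, 0), (1, 1, 1), (2, 2, 2))

    @pytest.mark.parametrize("seed", range(5))
    def test_normal_matches_cross_product_oracle(self, seed):
        rng = np.random.default_rng(seed)
        while True:
            s, n, b = rng.uniform(-100, 100, size=(3, 3))
            if np.linalg.norm(np.cross(n - s, b - s)) > 1e-3:
                break
        pl = midsagittal_plane(s, n, b)
        oracle = np.cross(n - s, b - s)
        oracle /= np.linalg.norm(oracle)
        assert np.allclose(pl.normal, oracle, atol=1e-12)
        assert abs(pl.signed_distance(s)) < 1e-9


class TestPlaneThroughTwoPointsNormalTo:
    def test_orthogonal_axes_case(self):
        ref = Plane(np.array([0.0, 0.0, 1.0]), 0.0)
        pl = plane_through_two_points_normal_to((0, 0, 0), (1, 0, 0), ref)
        assert np.allclose(pl.normal, [0, 1, 0])
        assert pl.offset == 0.0

    def test_coincident_points_rejected(self):
        ref = Plane(np.array([0.0, 0.0, 1.0]), 0.0)
        with pytest.raises(DegenerateGeometryError):
            plane_through_two_points_normal_to((1, 2, 3), (1, 2, 3), ref)

    def test_chord_parallel_to_reference_normal_rejected(self):
        ref = Plane(np.array([0.0, 0.0, 1.0]), 0.0)
        with pytest.raises(DegenerateGeometryError):
            plane_through_two_points_normal_to((0, 0, 0), (0, 0, 5), ref)

    @pytest.mark.parametrize("seed", range(5))
    def test_cross_product_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        p, q = rng.uniform(-50, 50, size=(2, 3))
        ref = Plane.from_normal_point(rng.standard_normal(3),
                                      rng.uniform(-50, 50, 3))
        pl = plane_through_two_points_normal_to(p, q, ref)
        oracle = np.cross(ref.normal, q - p)
        oracle /= np.linalg.norm(oracle)
        assert np.allclose(pl.normal, oracle, atol=1e-12)
        assert abs(pl.signed_distance(p)) < 1e-9
        assert abs(pl.signed_distance(q)) < 1e-9
        # perpendicular to the reference plane
        assert abs(pl.normal @ ref.normal) < 1e-9


class TestPlaneThroughThreePoints:
    def test_unit_triangle(self):
        pl = plane_through_three_points((0, 0, 0), (1, 0, 0), (0, 1, 0))
        assert np.allclose(pl.normal, [0, 0, 1])
        assert pl.offset == pytest.approx(0.0, abs=1e-12)

    def test_permutation_invariance(self):
        pts = [np.array([3.0, 1.0, -2.0]), np.array([-1.0, 4.0, 0.5]),
               np.array([2.0, -3.0, 1.0])]
        import itertools
        planes = [plane_through_three_points(*perm)
                  for perm in itertools.permutations(pts)]
        for pl in planes[1:]:
            assert np.allclose(pl.normal, planes[0].normal, atol=1e-12)
            assert pl.offset == pytest.approx(planes[0].offset, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_substitution_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        a, b, c = rng.uniform(-100, 100, size=(3, 3))
        pl = plane_through_three_points(a, b, c)
        for p in (a, b, c):
            assert abs(pl.signed_distance(p)) < 1e-9

    def test_collinear_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            plane_through_three_points((0, 0, 0), (1, 2, 3), (2, 4, 6))

    @settings(derandomize=True, max_examples=50)
    @given(hst.lists(hst.floats(-200, 200), min_size=9, max_size=9))
    def test_containment_property(self, coords):
        a, b, c = (np.asarray(coords[i:i + 3]) for i in (0, 3, 6))
        try:
            pl = plane_through_three_points(a, b, c)
        except DegenerateGeometryError:
            return  # near-collinear triples are legitimately rejected
        scale = max(np.abs(coords)) + 1.0
        for p in (a, b, c):
            assert abs(pl.signed_distance(p)) < 1e-9 * scale
        assert abs(np.linalg.norm(pl.normal) - 1.0) < 1e-9


class TestPlaneThroughPointParallelTo:
    def test_point_on_plane_returns_same_plane(self):
        ref = Plane.from_normal_point([0, 0, 1], [5, 5, 2])
        pl = plane_through_point_parallel_to([1, 1, 2], ref)
        assert pl.offset == pytest.approx(ref.offset)

    def test_translation_along_normal_shifts_offset(self):
        ref = Plane.from_normal_point([0.6, 0.8, 0.0], [1, 2, 3])
        p = np.array([1, 2, 3]) + 4.5 * ref.normal
        pl = plane_through_point_parallel_to(p, ref)
        assert pl.offset - ref.offset == pytest.approx(4.5, abs=1e-9)

    def test_substitution_oracle(self):
        rng = np.random.default_rng(4)
        ref = Plane.from_normal_point(rng.standard_normal(3),
                                      rng.uniform(-10, 10, 3))
        p = rng.uniform(-100, 100, 3)
        assert abs(plane_through_point_parallel_to(p, ref).signed_distance(p)) \
            < 1e-9


class TestBisectingPlane:
    def test_perpendicular_parents_bisect_at_45_degrees(self):
        p1 = Plane(np.array([1.0, 0.0, 0.0]), 0.0)
        p2 = Plane(np.array([0.0, 1.0, 0.0]), 0.0)
        pl = bisecting_plane(p1, p2, (0, 0, 0))
        assert np.allclose(pl.normal, [1 / np.sqrt(2), 1 / np.sqrt(2), 0])
        assert pl.offset == 0.0

    def test_identical_parents_returned_unchanged(self):
        p = Plane.from_normal_point([0, 0, 1], [1, 1, 5])
        out = bisecting_plane(p, p, (1, 1, 5))
        assert np.allclose(out.normal, p.normal)
        assert out.offset == pytest.approx(p.offset)

    def test_anchor_off_planes_rejected(self):
        p1 = Plane(np.array([1.0, 0.0, 0.0]), 0.0)
        p2 = Plane(np.array([0.0, 1.0, 0.0]), 0.0)
        with pytest.raises(ValueError):
            bisecting_plane(p1, p2, (5, 5, 5))

    @pytest.mark.parametrize("seed", range(8))
    def test_equal_dihedral_angles(self, seed):
        rng = np.random.default_rng(300 + seed)
        anchor = rng.uniform(-20, 20, 3)
        p1 = Plane.from_normal_point(rng.standard_normal(3), anchor)
        p2 = Plane.from_normal_point(rng.standard_normal(3), anchor)
        pl = bisecting_plane(p1, p2, anchor)
        a1, a2 = angle_between_planes(pl, p1), angle_between_planes(pl, p2)
        assert abs(a1 - a2) < 1e-9

    @pytest.mark.parametrize("seed", range(4))
    def test_wedge_point_selects_interior_bisector(self, seed):
        rng = np.random.default_rng(400 + seed)
        anchor = rng.uniform(-20, 20, 3)
        p1 = Plane.from_normal_point(rng.standard_normal(3), anchor)
        p2 = Plane.from_normal_point(rng.standard_normal(3), anchor)
        # interior direction: mean of the two normals oriented to agree
        n1, n2 = p1.normal, (p2.normal if p1.normal @ p2.normal >= 0
                             else -p2.normal)
        probe = anchor + np.cross(n1, n2) * 0 + (n1 + n2)
        pl = bisecting_plane(p1, p2, anchor, wedge_point=probe)
        a1, a2 = angle_between_planes(pl, p1), angle_between_planes(pl, p2)
        assert abs(a1 - a2) < 1e-9
        # the probe is equidistant from both parents; it lies on the
        # returned (interior) bisector plane up to numerical tolerance
        d1 = abs(float(p1.signed_distance(probe)))
        d2 = abs(float(p2.signed_distance(probe)))
        assert d1 == pytest.approx(d2, abs=1e-9)
        assert abs(float(pl.signed_distance(probe))) < 1e-9


class TestReferenceFrame:
    def test_spec_tilt_example(self):
        """Canonical S/N/Ba triple: the horizontal normal sits exactly six
        degrees from the pre-tilt normal (0, 1, 0)."""
        lms = {
            "S": (0, 0, 0), "N": (100, 0, 0), "Ba": (-30, -40, 0),
            "Me": (90, -70, 0), "Bpt": (90, -60, 0), "MSp": (85, -62, 2),
            "Co_L": (10, -40, 30), "Co_R": (10, -40, -30),
            "Go_L": (20, -60, 25), "Go_R": (20, -60, -25),
            "Cp_L": (15, -45, 28), "Cp_R": (15, -45, -28),
        }
        frame = build_reference_frame(
            LandmarkSet({k: np.asarray(v, float) for k, v in lms.items()})
        )
        pre_tilt = np.array([0.0, 1.0, 0.0])
        angle = np.degrees(np.arccos(np.clip(
            frame.axis_superior @ pre_tilt, -1, 1)))
        assert angle == pytest.approx(6.0, abs=1e-9)
        # the plane is tilted below S-N: Nasion ends up on the superior side
        assert frame.horizontal.signed_distance(np.array([100.0, 0, 0])) > 0

    def test_axes_orthonormal_right_handed(self, canonical_frame):
        axes = np.array([canonical_frame.axis_anterior,
                         canonical_frame.axis_left,
                         canonical_frame.axis_superior])
        assert np.allclose(axes @ axes.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(axes) == pytest.approx(1.0, abs=1e-9)

    def test_all_reference_planes_contain_sella(self, canonical_landmarks,
                                                canonical_frame):
        S = canonical_landmarks["S"]
        for pl in (canonical_frame.horizontal, canonical_frame.vertical,
                   canonical_frame.midsagittal):
            assert abs(pl.signed_distance(S)) < 1e-9

    @pytest.mark.parametrize("seed", range(3))
    def test_rigid_equivariance(self, canonical_landmarks, seed):
        rng = np.random.default_rng(500 + seed)
        Q, t = random_rigid_transform(rng)
        f0 = build_reference_frame(canonical_landmarks)
        f1 = build_reference_frame(canonical_landmarks.transformed(Q, t))
        assert np.allclose(f1.origin, Q @ f0.origin + t, atol=1e-9)
        for name in ("axis_anterior", "axis_superior", "axis_left"):
            assert np.allclose(getattr(f1, name), Q @ getattr(f0, name),
                               atol=1e-9)

    def test_rotation_composition_oracle(self, canonical_landmarks):
        """A pre-rotated landmark set yields the frame predicted by
        composing the same rotation with the canonical-case frame."""
        rng = np.random.default_rng(42)
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        theta = 0.7
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        Q = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * K @ K
        f0 = build_reference_frame(canonical_landmarks)
        f1 = build_reference_frame(
            canonical_landmarks.transformed(Q, np.zeros(3)))
        assert np.allclose(f1.axis_superior, Q @ f0.axis_superior, atol=1e-9)
        assert np.allclose(f1.axis_left, Q @ f0.axis_left, atol=1e-9)


class TestMandibularPlanes:
    def test_symmetric_phantom_sides_mirror(self, canonical_planes):
        L, R = canonical_planes["L"], canonical_planes["R"]
        M = np.diag([-1.0, 1.0, 1.0])  # canonical median plane is x = 0
        for name in ("condylion_gonion", "c_point", "mandibular_angle"):
            pl, pr = getattr(L, name), getattr(R, name)
            assert np.allclose(M @ pl.normal, pr.normal, atol=1e-6)
            assert pl.offset == pytest.approx(pr.offset, abs=1e-6)
        for name in ("gonion_menton", "median"):
            assert np.allclose(getattr(L, name).normal,
                               getattr(R, name).normal)

    def test_c_point_normal_parallel_to_superior_axis(
            self, canonical_planes, canonical_frame):
        for side in ("L", "R"):
            assert np.allclose(canonical_planes[side].c_point.normal,
                               canonical_frame.axis_superior, atol=1e-12)

    def test_angle_plane_contains_gonion_and_bisects(
            self, canonical_landmarks, canonical_planes):
        for side in ("L", "R"):
            planes = canonical_planes[side]
            go = canonical_landmarks[f"Go_{side}"]
            assert abs(planes.mandibular_angle.signed_distance(go)) < 1e-6
            a1 = angle_between_planes(planes.mandibular_angle,
                                      planes.condylion_gonion)
            a2 = angle_between_planes(planes.mandibular_angle,
                                      planes.gonion_menton)
            assert abs(a1 - a2) < 1e-9
            # Condylion on the positive side (the ramus half-space)
            co = canonical_landmarks[f"Co_{side}"]
            assert planes.mandibular_angle.signed_distance(co) > 0

    def test_unit_normals_everywhere(self, canonical_planes):
        for side in ("L", "R"):
            for name in ("condylion_gonion", "c_point", "gonion_menton",
                         "median", "mandibular_angle"):
                n = getattr(canonical_planes[side], name).normal
                assert abs(np.linalg.norm(n) - 1.0) < 1e-9

    @pytest.mark.parametrize("seed", range(3))
    def test_rigid_equivariance_of_all_planes(self, canonical_landmarks,
                                              seed):
        rng = np.random.default_rng(600 + seed)
        Q, t = random_rigid_transform(rng)
        lms_t = canonical_landmarks.transformed(Q, t)
        f0 = build_reference_frame(canonical_landmarks)
        f1 = build_reference_frame(lms_t)
        for side in ("L", "R"):
            p0 = build_mandibular_planes(canonical_landmarks, f0, side)
            p1 = build_mandibular_planes(lms_t, f1, side)
            for name in ("condylion_gonion", "c_point", "gonion_menton",
                         "median", "mandibular_angle"):
                expected = getattr(p0, name).transformed(Q, t)
                got = getattr(p1, name)
                assert np.allclose(got.normal, expected.normal, atol=1e-9)
                assert got.offset == pytest.approx(expected.offset, abs=1e-6)

    def test_reflection_swaps_sides_exactly(self, canonical_landmarks):
        frame = build_reference_frame(canonical_landmarks)
        reflected = canonical_landmarks.reflected(frame.midsagittal)
        f_ref = build_reference_frame(reflected)
        for side, other in (("L", "R"), ("R", "L")):
            p0 = build_mandibular_planes(canonical_landmarks, frame, side)
            p1 = build_mandibular_planes(reflected, f_ref, other)
            M = np.eye(3) - 2 * np.outer(frame.midsagittal.normal,
                                         frame.midsagittal.normal)
            for name in ("condylion_gonion", "c_point", "mandibular_angle"):
                expected_normal = M @ getattr(p0, name).normal
                got = getattr(p1, name)
                assert np.allclose(np.abs(got.normal),
                                   np.abs(expected_normal), atol=1e-9)

    def test_alternative_bisector_parents(self, canonical_landmarks,
                                          canonical_frame):
        planes = build_mandibular_planes(
            canonical_landmarks, canonical_frame, "L",
            bisector_parents="condylion_gonion+c_point")
        a1 = angle_between_planes(planes.mandibular_angle,
                                  planes.condylion_gonion)
        a2 = angle_between_planes(planes.mandibular_angle, planes.c_point)
        assert abs(a1 - a2) < 1e-9


class TestLandmarkSetValidation:
    def test_missing_landmark_rejected(self, canonical_landmarks):
        partial = {n: canonical_landmarks[n]
                   for n in canonical_landmarks if n != "Me"}
        with pytest.raises(ValueError, match="Me"):
            LandmarkSet(partial)

    def test_coincident_landmarks_rejected(self, canonical_landmarks):
        bad = {n: canonical_landmarks[n] for n in canonical_landmarks}
        bad["N"] = bad["S"]
        with pytest.raises(ValueError, match="coincident"):
            LandmarkSet(bad)
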