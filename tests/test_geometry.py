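"""Geometry primitives: superposition, dihedrals, angles, hinge decomposition.

Independent oracles: biotite's superimpose/dihedral and scipy's Rotation
cross-check the in-package implementations on random instances.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ectodimer.geometry import (
    DegenerateGeometryError,
    GeometryError,
    HingeDecomposition,
    RigidTransform,
    centroid,
    decompose_hinge,
    dihedral,
    kabsch_superpose,
    rmsd_after_superposition,
    rotation_about_axis,
    vertex_angle,
)


def _random_points(rng, n=20, scale=20.0):
    return rng.uniform(-scale, scale, size=(n, 3))


class TestKabsch:
    def test_identity(self):
        pts = _random_points(np.random.default_rng(0))
        transform, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(transform.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(transform.translation, 0.0, atol=1e-9)

    def test_recovers_known_rotation_and_translation(self):
        rng = np.random.default_rng(1)
        target = _random_points(rng)
        rot = rotation_about_axis([0, 0, 1], 30.0)
        mobile = (target - target.mean(0)) @ rot + target.mean(0) + [5.0, 0.0, 0.0]
        transform, rmsd = kabsch_superpose(mobile, target)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        angle = np.degrees(np.arccos((np.trace(transform.rotation) - 1) / 2))
        assert angle == pytest.approx(30.0, abs=1e-9)

    def test_noisy_superposition_rmsd_matches_noise_scale(self):
        # Monte-Carlo oracle: with isotropic noise sigma the residual RMSD
        # after fitting approaches sigma (up to the fitted dof correction)
        rng = np.random.default_rng(42)
        target = _random_points(rng, n=100)
        sigma = 0.5
        mobile = target + rng.normal(scale=sigma, size=target.shape)
        transform, rmsd = kabsch_superpose(mobile, target)
        # per-atom deviation is 3D, so the expected RMSD is sigma * sqrt(3)
        assert rmsd == pytest.approx(sigma * np.sqrt(3), rel=0.15)
        assert np.allclose(transform.rotation, np.eye(3), atol=0.05)

    def test_agrees_with_biotite_superimpose(self):
        biotite_struc = pytest.importorskip("biotite.structure")
        rng = np.random.default_rng(7)
        a, b = _random_points(rng, 30), _random_points(rng, 30)
        fitted, _ = biotite_struc.superimpose(b, a)
        oracle = np.sqrt(np.mean(np.sum((np.asarray(fitted) - b) ** 2, axis=1)))
        # biotite computes in float32
        assert rmsd_after_superposition(a, b) == pytest.approx(float(oracle), abs=1e-4)

    def test_never_increases_rmsd(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            a, b = _random_points(rng), _random_points(rng)
            raw = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
            assert rmsd_after_superposition(a, b) <= raw + 1e-12

    def test_errors(self):
        with pytest.raises(GeometryError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line)

    def test_rigid_invariance_gives_zero(self):
        rng = np.random.default_rng(3)
        a = _random_points(rng)
        rot = rotation_about_axis(rng.normal(size=3), 77.0)
        moved = a @ rot.T + [1.0, -2.0, 3.0]
        assert rmsd_after_superposition(moved, a) == pytest.approx(0.0, abs=1e-9)


class TestDihedral:
    @pytest.mark.parametrize(
        "p4,expected_abs",
        [((1, 1, 0), 0.0), ((1, -1, 0), 180.0), ((1, 0, 1), 90.0), ((1, 0, -1), 90.0)],
    )
    def test_planar_and_orthogonal_cases(self, p4, expected_abs):
        value = dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), p4)
        assert abs(value) == pytest.approx(expected_abs, abs=1e-9)

    def test_reversal_preserves_and_reflection_flips_sign(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(-5, 5, size=(4, 3))
        forward = dihedral(*p)
        assert dihedral(*p[::-1]) == pytest.approx(forward, abs=1e-9)
        reflected = p * np.array([1.0, 1.0, -1.0])
        assert dihedral(*reflected) == pytest.approx(-forward, abs=1e-9)

    def test_agrees_with_biotite(self):
        biotite_struc = pytest.importorskip("biotite.structure")
        rng = np.random.default_rng(9)
        for _ in range(25):
            p = rng.uniform(-10, 10, size=(4, 3))
            oracle = np.degrees(biotite_struc.dihedral(p[0], p[1], p[2], p[3]))
            assert dihedral(*p) == pytest.approx(float(oracle), abs=1e-3)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateGeometryError):
            dihedral((0, 1, 0), (0, 0, 0), (0, 0, 0), (1, 1, 0))
        with pytest.raises(DegenerateGeometryError):
            dihedral((2, 0, 0), (1, 0, 0), (0, 0, 0), (1, 1, 0))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_invariant_under_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(-10, 10, size=(4, 3))
        try:
            before = dihedral(*p)
        except DegenerateGeometryError:
            return
        rot = rotation_about_axis(rng.normal(size=3) + 1e-3, float(rng.uniform(0, 360)))
        trans = rng.uniform(-100, 100, size=3)
        after = dihedral(*(p @ rot.T + trans))
        assert after == pytest.approx(before, abs=1e-6)


class TestVertexAngleAndCentroid:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((1, 0, 0), (0, 1, 0), 90.0),
            ((1, 0, 0), (-1, 0, 0), 180.0),
            ((1, 0, 0), (1, 0, 0), 0.0),
        ],
    )
    def test_reference_angles(self, a, b, expected):
        assert vertex_angle(a, (0, 0, 0), b) == pytest.approx(expected, abs=1e-9)

    def test_zero_length_ray_raises(self):
        with pytest.raises(GeometryError):
            vertex_angle((0, 0, 0), (0, 0, 0), (1, 0, 0))

    def test_centroid_cases(self):
        assert np.allclose(centroid([(1.0, 2.0, 3.0)]), (1, 2, 3))
        assert np.allclose(centroid([(0, 0, 0), (2, 4, 6)]), (1, 2, 3))
        rng = np.random.default_rng(2)
        cloud = rng.normal(size=(50, 3))
        sym = np.vstack([cloud, -cloud])
        assert np.allclose(centroid(sym), 0.0, atol=1e-12)
        with pytest.raises(GeometryError):
            centroid(np.empty((0, 3)))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_vertex_angle_rigid_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a, v, b = rng.uniform(-10, 10, size=(3, 3))
        if np.linalg.norm(a - v) < 1e-6 or np.linalg.norm(b - v) < 1e-6:
            return
        before = vertex_angle(a, v, b)
        rot = rotation_about_axis(rng.normal(size=3) + 1e-3, float(rng.uniform(0, 360)))
        trans = rng.uniform(-100, 100, size=3)
        moved = np.array([a, v, b]) @ rot.T + trans
        assert vertex_angle(*moved) == pytest.approx(before, abs=1e-6)


class TestRigidTransformAndHinge:
    def test_rotations_are_proper_orthogonal(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            rot = rotation_about_axis(rng.normal(size=3) + 1e-3, float(rng.uniform(0, 360)))
            t = RigidTransform(rot, rng.normal(size=3))
            assert abs(np.linalg.det(t.rotation) - 1) < 1e-9
            assert np.abs(t.rotation @ t.rotation.T - np.eye(3)).max() < 1e-9

    def test_improper_rotation_rejected(self):
        with pytest.raises(GeometryError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_compose_and_inverse(self):
        rng = np.random.default_rng(17)
        t1 = RigidTransform(rotation_about_axis([0, 0, 1], 40.0), rng.normal(size=3))
        t2 = RigidTransform(rotation_about_axis([0, 1, 0], 25.0), rng.normal(size=3))
        pts = rng.normal(size=(10, 3))
        assert np.allclose(t1.compose(t2).apply(pts), t1.apply(t2.apply(pts)))
        assert np.allclose(t1.inverse().apply(t1.apply(pts)), pts, atol=1e-9)

    def test_hinge_decomposition_known_axis(self):
        t = RigidTransform(rotation_about_axis([0, 0, 1], 25.0), np.zeros(3))
        h = decompose_hinge(t, pivot=[1.0, 2.0, 3.0])
        assert h.angle == pytest.approx(25.0, abs=1e-9)
        assert np.allclose(np.abs(h.axis), [0, 0, 1], atol=1e-9)

    def test_hinge_identity_flagged(self):
        h = decompose_hinge(RigidTransform.identity(), pivot=np.zeros(3))
        assert h.angle == 0.0
        assert not h.axis_defined

    def test_hinge_composition_adds_angles(self):
        r1 = rotation_about_axis([0, 1, 0], 10.0)
        r2 = rotation_about_axis([0, 1, 0], 15.0)
        t = RigidTransform(r2 @ r1, np.zeros(3))
        assert decompose_hinge(t, np.zeros(3)).angle == pytest.approx(25.0, abs=1e-9)

    def test_hinge_agrees_with_scipy_rotation(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(23)
        for _ in range(10):
            rot = Rotation.random(random_state=rng)
            h = decompose_hinge(RigidTransform(rot.as_matrix(), np.zeros(3)), np.zeros(3))
            assert h.angle == pytest.approx(np.degrees(rot.magnitude()), abs=1e-6)
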