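"""Rigid landmark registration: Kabsch fit, RMSD, transforms."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from stereonav.errors import DegenerateConfigurationError, InsufficientLandmarksError
from stereonav.overlay import SurfaceMesh
from stereonav.register import (
    LandmarkSet,
    RigidTransform,
    apply_transform,
    fit_rigid,
    rmsd,
)


def quaternion_fit(moving: np.ndarray, fixed: np.ndarray):
    """Independent oracle: Horn's closed-form quaternion method.

    Builds the 4x4 symmetric matrix from the cross-covariance of the
    centered point sets; the eigenvector of the largest eigenvalue is the
    unit quaternion of the optimal rotation.
    """
    mu_m, mu_f = moving.mean(axis=0), fixed.mean(axis=0)
    a, b = moving - mu_m, fixed - mu_f
    s = a.T @ b
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    n = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    vals, vecs = np.linalg.eigh(n)
    q = vecs[:, np.argmax(vals)]  # (w, x, y, z)
    r = Rotation.from_quat([q[1], q[2], q[3], q[0]]).as_matrix()
    return r, mu_f - r @ mu_m


def random_transform(rng) -> RigidTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    r = Rotation.from_rotvec(axis * rng.uniform(0, np.pi)).as_matrix()
    return RigidTransform(r, rng.uniform(-50, 50, 3))


class TestFitRigid:
    def test_identity_on_identical_sets(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        res = fit_rigid(pts, pts)
        assert np.allclose(res.transform.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(res.transform.translation, 0, atol=1e-12)
        assert res.rmsd_mm == pytest.approx(0.0, abs=1e-12)

    def test_recovers_constructed_transform(self):
        # 90 degrees about z plus translation; six non-collinear landmarks,
        # the typical landmark count in this registration setting
        r0 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        t0 = np.array([10.0, -5.0, 3.0])
        rng = np.random.default_rng(1)
        moving = rng.uniform(-20, 20, (6, 3))
        fixed = moving @ r0.T + t0
        res = fit_rigid(moving, fixed)
        assert np.allclose(res.transform.rotation, r0, atol=1e-12)
        assert np.allclose(res.transform.translation, t0, atol=1e-10)
        assert res.rmsd_mm < 1e-9

    def test_reflection_suppressed(self):
        """Mirrored data still yields a proper rotation (det = +1)."""
        rng = np.random.default_rng(2)
        moving = rng.uniform(-10, 10, (8, 3))
        fixed = moving * np.array([-1.0, 1.0, 1.0])  # mirror in x
        res = fit_rigid(moving, fixed)
        assert np.linalg.det(res.transform.rotation) == pytest.approx(1.0, abs=1e-10)
        assert res.rmsd_mm > 0

    def test_agrees_with_quaternion_oracle(self):
        """SVD fit matches Horn's quaternion method on random noisy instances."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(3, 11)
            moving = rng.uniform(-30, 30, (n, 3))
            truth = random_transform(rng)
            fixed = truth.apply(moving) + rng.normal(0, 1.0, (n, 3))
            res = fit_rigid(moving, fixed)
            r_o, t_o = quaternion_fit(moving, fixed)
            assert np.allclose(res.transform.rotation, r_o, atol=1e-9)
            assert np.allclose(res.transform.translation, t_o, atol=1e-9)

    @pytest.mark.parametrize("n", range(3, 11))
    def test_noiseless_parameter_recovery(self, n):
        rng = np.random.default_rng(100 + n)
        moving = rng.uniform(-25, 25, (n, 3))
        truth = random_transform(rng)
        res = fit_rigid(moving, truth.apply(moving))
        assert res.rmsd_mm < 1e-9
        err = Rotation.from_matrix(res.transform.rotation.T @ truth.rotation).magnitude()
        assert err < 1e-8
        assert np.linalg.norm(res.transform.translation - truth.translation) < 1e-8

    def test_rmsd_after_fit_never_worse(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = rng.integers(3, 9)
            moving = rng.uniform(-20, 20, (n, 3))
            fixed = rng.uniform(-20, 20, (n, 3))
            res = fit_rigid(moving, fixed)
            assert res.rmsd_mm <= rmsd(moving, fixed) + 1e-12

    def test_noise_scaling_law(self):
        """Mean RMSD^2 under isotropic fixed-set noise is sigma^2 (3n-6)/n.

        Six rigid degrees of freedom are absorbed by the fit; at sigma =
        4.7 mm and n = 6 the expected RMSD is ~6.6 mm.
        """
        sigma, n, reps = 4.7, 6, 400
        rng = np.random.default_rng(2024)
        base = rng.uniform(-40, 40, (n, 3))
        vals = []
        for _ in range(reps):
            truth = random_transform(rng)
            fixed = truth.apply(base) + rng.normal(0, sigma, (n, 3))
            vals.append(fit_rigid(base, fixed).rmsd_mm)
        expected = np.sqrt(sigma**2 * (3 * n - 6) / n)
        assert np.mean(vals) == pytest.approx(expected, rel=0.10)

    def test_too_few_landmarks(self):
        with pytest.raises(InsufficientLandmarksError):
            fit_rigid(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_moving_set(self):
        line = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateConfigurationError):
            fit_rigid(line, line + 1.0)

    def test_landmark_sets_as_inputs(self):
        moving = LandmarkSet([[0, 0, 0], [5, 0, 0], [0, 5, 0], [0, 0, 5.0]], frame="preop")
        res = fit_rigid(moving, moving)
        assert res.n_landmarks == 4
        assert res.rmsd_mm == pytest.approx(0.0, abs=1e-12)


class TestRmsd:
    def test_identical(self):
        pts = np.ones((4, 3))
        assert rmsd(pts, pts) == 0.0

    def test_hand_value(self):
        a = np.zeros((2, 3))
        b = np.array([[3.0, 0, 0], [0, 4.0, 0]])
        assert rmsd(a, b) == pytest.approx(np.sqrt(12.5))

    def test_isometry_invariance(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=(10, 3)), rng.normal(size=(10, 3))
        t = random_transform(rng)
        assert abs(rmsd(t.apply(a), t.apply(b)) - rmsd(a, b)) < 1e-10

    def test_cardinality_mismatch(self):
        with pytest.raises(ValueError):
            rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


class TestTransforms:
    def test_identity_and_inverse(self):
        rng = np.random.default_rng(6)
        t = random_transform(rng)
        pts = rng.normal(size=(30, 3))
        assert np.allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-10)
        assert np.allclose(RigidTransform.identity().apply(pts), pts)

    def test_composition_matches_matrix_product(self):
        rng = np.random.default_rng(7)
        t1, t2 = random_transform(rng), random_transform(rng)
        composed = t2.compose(t1)
        assert np.allclose(composed.matrix(), t2.matrix() @ t1.matrix(), atol=1e-12)
        pts = rng.normal(size=(10, 3))
        assert np.allclose(t2.apply(t1.apply(pts)), composed.apply(pts), atol=1e-10)

    def test_apply_to_mesh_preserves_faces(self):
        mesh = SurfaceMesh(
            np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0.0]]), np.array([[0, 1, 2]]), label="vein"
        )
        t = RigidTransform(np.eye(3), [1.0, 2.0, 3.0])
        out = apply_transform(mesh, t)
        assert np.array_equal(out.faces, mesh.faces)
        assert out.label == "vein"
        assert np.allclose(out.vertices, mesh.vertices + [1, 2, 3])

    def test_apply_to_landmarks_preserves_names(self):
        lm = LandmarkSet([[0, 0, 0.0]], ["A7"], frame="preop")
        out = apply_transform(lm, RigidTransform(np.eye(3), [0, 0, 1.0]))
        assert out.names == ["A7"]
        assert np.allclose(out.points, [[0, 0, 1.0]])

    def test_improper_rotation_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))
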