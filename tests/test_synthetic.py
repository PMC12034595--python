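"""Synthetic scene generators: rigs, boards, trees, renders, perturbation."""

import numpy as np
import pytest

from stereonav.camera import CheckerboardSpec, project_point
from stereonav.overlay import SurfaceMesh
from stereonav.register import fit_rigid
from stereonav.render import value_noise3
from stereonav.synthetic import (
    make_checkerboard_views,
    make_rig,
    make_scene,
    make_vessel_tree,
    perturb_scene,
    render_synthetic_stereo,
)


def _round_sig(x, sig=5):
    from math import floor, log10

    return 0.0 if x == 0 else round(x, -int(floor(log10(abs(x)))) + (sig - 1))


class TestMakeRig:
    def test_vats_preset_reproduces_printed_q(self):
        q = make_rig("vats").q_matrix
        assert q[0, 3] == -988.53
        assert q[1, 3] == -546.98
        assert q[2, 3] == 1432.8
        assert _round_sig(q[3, 2]) == 0.16406
        assert q[3, 3] == 0.0

    def test_rats_preset_reproduces_printed_q(self):
        rig = make_rig("rats")
        assert rig.left.image_size == (1264, 1010)
        q = rig.q_matrix
        assert q[0, 3] == -672.0
        assert q[2, 3] == 1013.3
        assert _round_sig(q[3, 2]) == 0.25266

    def test_custom_invalid_focal(self):
        with pytest.raises(Exception):
            make_rig("custom", focal_px=-1.0, principal=(0, 0), image_size=(10, 10), baseline_mm=5)

    def test_unknown_preset(self):
        with pytest.raises(ValueError):
            make_rig("hubble")


class TestCheckerboard:
    def test_nine_by_seven_squares_has_48_corners(self):
        board = CheckerboardSpec.from_squares(9, 7, 6.0)
        assert board.inner_corner_grid == (8, 6)
        assert board.corner_count == 48
        # config flag: counts already refer to inner corners
        board2 = CheckerboardSpec.from_squares(9, 7, 6.0, counts_inner_corners=True)
        assert board2.corner_count == 63

    def test_zero_noise_matches_exact_projection(self):
        rig = make_rig("desk")
        board = CheckerboardSpec.from_squares(9, 7, 6.0)
        obs = make_checkerboard_views(rig, board, 3, seed=5)
        obj = board.object_points()
        for (lpx, rpx), (r, t) in zip(obs.views, obs.poses):
            assert np.allclose(lpx, project_point(rig.left, obj @ r.T + t), atol=1e-12)
            assert lpx.shape == (48, 2)

    def test_fixed_seed_reproducible(self):
        rig = make_rig("desk")
        board = CheckerboardSpec.from_squares(9, 7, 6.0)
        a = make_checkerboard_views(rig, board, 4, seed=9, corner_noise_px=0.3)
        b = make_checkerboard_views(rig, board, 4, seed=9, corner_noise_px=0.3)
        for (la, ra), (lb, rb) in zip(a.views, b.views):
            assert np.array_equal(la, lb) and np.array_equal(ra, rb)


class TestVesselTree:
    def test_depth_zero_single_tube_no_landmarks(self):
        mesh, lm = make_vessel_tree(0, depth=0)
        assert len(lm) == 0
        assert len(mesh.faces) > 0

    def test_depth_two_has_three_bifurcations(self):
        _, lm = make_vessel_tree(1, depth=2)
        assert len(lm) == 3
        assert len(set(lm.names)) == 3

    def test_landmarks_near_centerline_join(self):
        """Each bifurcation landmark lies within one radius of the mesh."""
        mesh, lm = make_vessel_tree(2, depth=2, root_radius_mm=2.0)
        for p in lm.points:
            d = np.linalg.norm(mesh.vertices - p, axis=1).min()
            assert d <= 2.0 + 1e-9

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            make_vessel_tree(0, depth=-1)
        with pytest.raises(ValueError):
            make_vessel_tree(0, root_radius_mm=0.0)


class TestRenderStereo:
    def test_fronto_parallel_plane_exact_disparity(self):
        rig = make_rig("desk")
        f, b = rig.rectified_focal, rig.baseline_mm
        d0 = 30.0
        z = f * b / d0
        half = 40.0
        plane = SurfaceMesh(
            [[-half, -half, z], [half, -half, z], [half, half, z], [-half, half, z]],
            [[0, 1, 2], [0, 2, 3]],
            label="surface",
        )
        frame, tdisp, tdepth, occ = render_synthetic_stereo([plane], rig, seed=0)
        d = tdisp.disparity[tdisp.valid_mask]
        assert len(d) > 1000
        assert np.allclose(d, d0, atol=1e-4)

    def test_disparity_vanishes_at_infinity(self):
        rig = make_rig("desk")
        for z, bound in ((500.0, 10.0), (5000.0, 1.0)):
            plane = SurfaceMesh(
                [[-900, -900, z], [900, -900, z], [900, 900, z], [-900, 900, z]],
                [[0, 1, 2], [0, 2, 3]],
                label="surface",
            )
            _, tdisp, _, _ = render_synthetic_stereo([plane], rig, seed=0)
            assert np.nanmax(tdisp.disparity) < bound

    def test_disparity_depth_consistency(self, default_scene):
        scene = default_scene
        f, b = scene.rig.rectified_focal, scene.rig.baseline_mm
        m = scene.true_disparity.valid_mask
        lhs = scene.true_disparity.disparity[m] * scene.true_depth[m]
        assert np.max(np.abs(lhs - f * b)) < 1e-3  # float32 disparity storage

    def test_occluder_produces_mask_and_matcher_gap(self):
        scene = make_scene(seed=5, n_occluders=1)
        assert scene.occlusion_mask.sum() > 200

    def test_empty_geometry_rejected(self):
        rig = make_rig("desk")
        with pytest.raises(ValueError):
            render_synthetic_stereo([], rig)

    def test_texture_is_stereo_consistent(self):
        """The same 3D point renders to the same value in both eyes."""
        rng = np.random.default_rng(0)
        pts = rng.uniform(-50, 50, (500, 3))
        a = value_noise3(pts, 2.0, seed=7)
        b = value_noise3(pts.copy(), 2.0, seed=7)
        assert np.array_equal(a, b)
        assert a.min() >= 0 and a.max() <= 1


class TestSceneAndPerturb:
    def test_scene_deterministic(self):
        a = make_scene(seed=11)
        b = make_scene(seed=11)
        assert np.array_equal(a.frame.left_image, b.frame.left_image)
        assert np.array_equal(a.landmark_pixels, b.landmark_pixels)

    def test_landmarks_within_one_radius_of_centerline(self):
        scene = make_scene(seed=3)
        # snapped surface landmarks stay near their centerline nodes
        # (within the root tube radius of the study tree)
        tree_cam = scene.meshes_camera[0]
        for p in scene.landmarks_intraop_true.points:
            assert np.linalg.norm(tree_cam.vertices - p, axis=1).min() < 2.2

    def test_exact_pairs_satisfy_displacement(self):
        scene = perturb_scene(make_scene(seed=4), seed=44)
        moved = scene.displacement.apply(scene.landmarks_preop.points)
        assert np.allclose(moved, scene.landmarks_intraop_true.points, atol=1e-9)

    def test_sigma_zero_fit_recovers_displacement(self):
        scene = perturb_scene(make_scene(seed=4), landmark_noise_sigma_mm=0.0, seed=44)
        res = fit_rigid(scene.landmarks_preop, scene.landmarks_intraop)
        assert res.rmsd_mm < 1e-9
        assert np.allclose(res.transform.rotation, scene.displacement.rotation, atol=1e-8)
        assert np.allclose(res.transform.translation, scene.displacement.translation, atol=1e-7)

    def test_perturbation_reproducible(self):
        base = make_scene(seed=4)
        a = perturb_scene(base, landmark_noise_sigma_mm=1.0, seed=5)
        b = perturb_scene(base, landmark_noise_sigma_mm=1.0, seed=5)
        assert np.array_equal(a.landmarks_intraop.points, b.landmarks_intraop.points)
        assert np.allclose(a.displacement.matrix(), b.displacement.matrix())

    def test_noise_law_through_scene_pairs(self):
        """sigma = 4.7 mm on n landmark pairs reproduces the RMSD law."""
        base = make_scene(seed=6)
        n = len(base.landmarks_intraop_true)
        sigma, reps = 4.7, 200
        vals = []
        for i in range(reps):
            sc = perturb_scene(base, landmark_noise_sigma_mm=sigma, seed=i)
            vals.append(fit_rigid(sc.landmarks_preop, sc.landmarks_intraop).rmsd_mm)
        expected = np.sqrt(sigma**2 * (3 * n - 6) / n)
        assert np.mean(vals) == pytest.approx(expected, rel=0.10)
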