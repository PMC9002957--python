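import itertools

import numpy as np
from hypothesis import given, settings, strategies as st

from mvkin.cameras import make_rig, project
from mvkin.simulate import CorruptionSpec, MotionSpec, generate_motion, observe
from mvkin.triangulate import (
    robust_triangulate,
    triangulate_point,
    triangulate_sequence,
)


def observations_of(point, rig, confidences=None):
    confidences = confidences or [1.0] * len(rig)
    obs = []
    for cam, c in zip(rig, confidences):
        uv = project(point, cam)
        obs.append((uv[0], uv[1], c, cam))
    return obs


def exhaustive_best_subset(obs, max_reproj_error):
    """Oracle: largest camera subset whose DLT fit meets the threshold."""
    best = None
    n = len(obs)
    for size in range(n, 1, -1):
        for subset in itertools.combinations(range(n), size):
            sub = [obs[i] for i in subset]
            r = triangulate_point(sub)
            if r.valid and r.mean_residual <= max_reproj_error:
                if best is None or r.mean_residual < best[1]:
                    best = (r.position, r.mean_residual, subset)
        if best is not None:
            return best
    return None


class TestTriangulatePoint:
    def test_noiseless_round_trip(self):
        rig = make_rig(2, 4.0)
        p = np.array([0.1, 1.2, 0.3])
        r = triangulate_point(observations_of(p, rig))
        assert np.allclose(r.position, p, atol=1e-9)
        assert r.mean_residual < 1e-6

    def test_confidence_weighting_pulls_toward_reliable_camera(self):
        rig = make_rig(3, 4.0)
        p = np.array([0.05, 1.1, -0.1])
        obs = observations_of(p, rig, confidences=[1.0, 1.0, 0.35])
        u, v, c, cam = obs[2]
        noisy = list(obs)
        noisy[2] = (u + 8.0, v - 5.0, c, cam)  # noise only on the doubted view
        unweighted = [(o[0], o[1], 1.0, o[3]) for o in noisy]
        err_w = np.linalg.norm(triangulate_point(noisy).position - p)
        err_u = np.linalg.norm(triangulate_point(unweighted).position - p)
        assert err_w < err_u

    def test_single_usable_observation_is_invalid(self):
        rig = make_rig(2, 4.0)
        obs = observations_of(np.array([0, 1, 0.2]), rig, confidences=[1.0, 0.0])
        r = triangulate_point(obs)
        assert not r.valid and r.position is None

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        x=st.floats(-0.5, 0.5),
        y=st.floats(0.3, 1.8),
        z=st.floats(-0.5, 0.5),
        k=st.floats(0.5, 3.0),
    )
    def test_scale_equivariance(self, x, y, z, k):
        """Scaling the scene and camera translations by k scales the output by k."""
        rig = make_rig(4, 3.0)
        p = np.array([x, y, z])
        r1 = triangulate_point(observations_of(p, rig))
        scaled_rig = [
            type(c)(
                c.focal_lengths,
                c.principal_point,
                c.rotation,
                c.translation * k,
                c.image_size,
            )
            for c in rig
        ]
        r2 = triangulate_point(observations_of(p * k, scaled_rig))
        assert np.allclose(r2.position, r1.position * k, atol=1e-8 * k)


class TestRobustTriangulate:
    def test_corrupted_camera_excluded_matches_oracle(self):
        rng = np.random.default_rng(0)
        rig = make_rig(8, 4.0)
        for _ in range(20):
            p = rng.uniform([-0.5, 0.3, -0.5], [0.5, 1.8, 0.5])
            obs = observations_of(p, rig)
            bad = rng.integers(0, 8)
            u, v, c, cam = obs[bad]
            obs[bad] = (u + 100.0, v, c, cam)
            r = robust_triangulate(obs, max_reproj_error=15.0)
            oracle = exhaustive_best_subset(obs, 15.0)
            assert bad not in r.cameras_used
            assert np.allclose(r.position, oracle[0], atol=1e-6)

    def test_consistent_cameras_match_plain_dlt(self):
        rig = make_rig(8, 4.0)
        p = np.array([0.2, 1.0, -0.3])
        obs = observations_of(p, rig)
        r = robust_triangulate(obs)
        r0 = triangulate_point(obs)
        assert r.cameras_used == list(range(8))
        assert np.allclose(r.position, r0.position, atol=1e-12)
        assert not r.low_quality

    def test_two_inconsistent_cameras_terminate_flagged(self):
        rig = make_rig(3, 4.0)
        p = np.array([0.0, 1.0, 0.0])
        obs = observations_of(p, rig)
        # corrupt two views in conflicting directions
        u, v, c, cam = obs[0]
        obs[0] = (u + 80.0, v, c, cam)
        u, v, c, cam = obs[1]
        obs[1] = (u - 80.0, v + 60.0, c, cam)
        r = robust_triangulate(obs, max_reproj_error=2.0)
        assert len(r.cameras_used) == 2
        assert r.low_quality


class TestTriangulateSequence:
    def test_noiseless_pipeline_is_exact(self, walking_truth, clean_trajectory):
        assert clean_trajectory.valid.all()
        err = np.linalg.norm(
            clean_trajectory.positions - walking_truth.keypoint_positions, axis=-1
        )
        assert err.max() < 1e-9

    def test_occluded_frames_fall_back_to_two_cameras(self, walking_truth, rig8):
        occ = [(c, "RAnkle", 10, 21) for c in range(6)]
        obs = observe(walking_truth, rig8, CorruptionSpec(occlusions=occ))
        traj = triangulate_sequence(obs, rig8)
        k = traj.keypoint_names.index("RAnkle")
        assert traj.valid[:, k].all()
        assert np.all(traj.n_cameras_used[10:21, k] == 2)
        assert np.all(traj.n_cameras_used[:10, k] == 8)

    def test_gap_filling_interpolates_short_runs_only(self, walking_truth, rig8):
        occ = [(c, "LWrist", 40, 43) for c in range(8)]  # 3-frame total dropout
        occ += [(c, "LElbow", 50, 60) for c in range(8)]  # 10-frame dropout
        obs = observe(walking_truth, rig8, CorruptionSpec(occlusions=occ))
        traj = triangulate_sequence(obs, rig8, max_gap=5)
        kw = traj.keypoint_names.index("LWrist")
        ke = traj.keypoint_names.index("LElbow")
        assert traj.valid[40:43, kw].all() and traj.interpolated[40:43, kw].all()
        # interpolated samples lie on the chord between the neighbors
        for a in range(3):
            chord = np.interp(
                [40, 41, 42], [39, 43], [traj.positions[39, kw, a], traj.positions[43, kw, a]]
            )
            assert np.allclose(traj.positions[40:43, kw, a], chord, atol=1e-12)
        assert not traj.valid[50:60, ke].any()

    def test_monotone_benefit_of_more_cameras(self, model):
        """Mean 3D error does not increase with more uncorrupted cameras."""
        rng = np.random.default_rng(7)
        truth = generate_motion(MotionSpec(n_cycles=1, seed=7), model)
        errors = []
        for n in (2, 4, 8):
            rig = make_rig(n, 4.0)
            per_seed = []
            for seed in range(30):
                obs = observe(truth, rig, CorruptionSpec(pixel_noise_sd=2.0, seed=seed))
                traj = triangulate_sequence(obs, rig)
                err = np.linalg.norm(
                    traj.positions - truth.keypoint_positions, axis=-1
                )
                per_seed.append(np.nanmean(err))
            errors.append(np.mean(per_seed))
        assert errors[0] >= errors[1] >= errors[2]
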