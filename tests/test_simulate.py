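import numpy as np
import pytest

from mvkin.simulate import (
    CorruptionSpec,
    GenerationError,
    MotionSpec,
    generate_motion,
    generate_reference_markers,
    observe,
    sample_systematic_offsets,
    static_trial,
)
from mvkin.triangulate import triangulate_sequence


class TestMotionSpec:
    def test_frame_rate_must_exceed_twice_cadence(self):
        with pytest.raises(GenerationError):
            MotionSpec(cadence=20.0, frame_rate=30.0)

    def test_amplitude_past_limit_names_the_dof(self):
        with pytest.raises(GenerationError, match="knee_flexion_r"):
            generate_motion(MotionSpec(angle_amplitudes={"knee_flexion_r": 80.0}))


class TestGenerateMotion:
    def test_frame_and_event_counts(self, walking_truth):
        # 3 cycles at 30 Hz / 1 Hz cadence -> 90 frames, 3 heel strikes
        assert walking_truth.q.shape[0] == 90
        assert len(walking_truth.event_frames) == 3

    def test_eight_cycles_give_240_frames_and_8_strikes(self, model):
        truth = generate_motion(MotionSpec(n_cycles=8), model)
        assert truth.q.shape[0] == 240
        assert len(truth.event_frames) == 8

    def test_angles_respect_overridden_amplitude_band(self, model):
        spec = MotionSpec(
            angle_amplitudes={"knee_flexion_r": 30.0},
            angle_offsets={"knee_flexion_r": 30.0},
            cycle_variability=0.0,
            n_cycles=2,
        )
        truth = generate_motion(spec, model)
        knee = truth.angles["knee_flexion_r"]
        assert knee.min() >= -1e-9 and knee.max() <= 60.0 + 1e-9

    def test_periodicity_at_the_cadence(self, model):
        spec = MotionSpec(n_cycles=4, cycle_variability=0.0, seed=3)
        truth = generate_motion(spec, model)
        hip = truth.angles["hip_flexion_r"]
        x = hip - hip.mean()
        ac = np.correlate(x, x, mode="full")[len(x) - 1 :]
        period = int(round(spec.frame_rate / spec.cadence))
        interior = ac[period // 2 : len(ac) - period // 2]
        assert np.argmax(interior) + period // 2 == period

    def test_determinism_same_seed_bit_identical(self, model):
        a = generate_motion(MotionSpec(seed=5, n_cycles=2), model)
        b = generate_motion(MotionSpec(seed=5, n_cycles=2), model)
        assert np.array_equal(a.q, b.q)
        assert np.array_equal(a.keypoint_positions, b.keypoint_positions)

    def test_ground_truth_angles_within_model_limits(self, walking_truth, model):
        for d in model.dofs:
            if d.kind == "limited" and d.name in walking_truth.angles:
                sig = walking_truth.angles[d.name]
                assert sig.min() >= d.bounds[0] - 1e-9
                assert sig.max() <= d.bounds[1] + 1e-9


class TestObserve:
    def test_noiseless_observations_have_unit_confidence(self, clean_observations):
        conf = clean_observations.uvc[..., 2]
        assert np.all((conf == 1.0) | (conf == 0.0))
        assert conf.mean() > 0.99

    def test_determinism(self, walking_truth, rig8):
        spec = CorruptionSpec(pixel_noise_sd=2.0, seed=9)
        a = observe(walking_truth, rig8, spec)
        b = observe(walking_truth, rig8, spec)
        assert np.array_equal(a.uvc, b.uvc)

    def test_occlusion_bookkeeping(self, walking_truth, rig8):
        occ = [(c, "RAnkle", 10, 21) for c in range(6)]
        obs = observe(walking_truth, rig8, CorruptionSpec(occlusions=occ))
        k = obs.keypoint_names.index("RAnkle")
        conf = obs.uvc[:, :, k, 2]
        assert np.all((conf[10:21] > 0).sum(axis=1) == 2)
        assert np.all((conf[:10] > 0).sum(axis=1) == 8)

    def test_world_frame_offset_shows_up_verbatim_in_triangulation(
        self, walking_truth, rig8
    ):
        off = (0.0, 0.03, 0.0)
        obs = observe(
            walking_truth,
            rig8,
            CorruptionSpec(systematic_offsets={"RHip": off}, offset_frame="world"),
        )
        traj = triangulate_sequence(obs, rig8)
        k = traj.keypoint_names.index("RHip")
        delta = traj.positions[:, k] - walking_truth.keypoint_positions[:, k]
        assert np.allclose(delta, off, atol=1e-9)

    def test_local_frame_offset_constant_in_reference_frame(self, rig8, model):
        # static trial: local and world frames coincide up to a fixed rotation,
        # so the triangulated bias must be constant over time
        truth = static_trial(model, n_frames=8)
        obs = observe(
            truth, rig8, CorruptionSpec(systematic_offsets={"RKnee": (0.02, 0, 0.01)})
        )
        traj = triangulate_sequence(obs, rig8)
        k = traj.keypoint_names.index("RKnee")
        delta = traj.positions[:, k] - truth.keypoint_positions[:, k]
        assert np.allclose(delta - delta[0], 0.0, atol=1e-9)
        assert np.linalg.norm(delta[0]) == pytest.approx(
            np.linalg.norm([0.02, 0, 0.01]), abs=1e-9
        )

    def test_offset_bound_enforced(self):
        with pytest.raises(ValueError):
            CorruptionSpec(systematic_offsets={"RHip": (0.2, 0, 0)})

    def test_confidence_encodes_pixel_error(self, walking_truth, rig8):
        obs = observe(walking_truth, rig8, CorruptionSpec(pixel_noise_sd=3.0, seed=4))
        conf = obs.uvc[..., 2]
        assert conf.min() >= 0.0 and conf.max() <= 1.0
        # inverse-linear model: mean confidence ~ 1 - E|noise|/20
        expected = 1.0 - 3.0 * np.sqrt(np.pi / 2) / 20.0
        assert conf[conf > 0].mean() == pytest.approx(expected, abs=0.01)


class TestReferenceMarkers:
    def test_noise_free_midpoints_equal_joint_centers(self, walking_truth):
        names, pos = generate_reference_markers(walking_truth, soft_tissue_sd=0.0)
        i_med = names.index("RAnkleMed")
        i_lat = names.index("RAnkleLat")
        mid = 0.5 * (pos[:, i_med] + pos[:, i_lat])
        k = walking_truth.keypoint_names.index("RAnkle")
        assert np.allclose(mid, walking_truth.keypoint_positions[:, k], atol=1e-12)

    def test_midpoint_noise_scales_like_average_of_two(self, walking_truth):
        sd = 0.005
        names, pos = generate_reference_markers(walking_truth, sd, seed=2)
        i_med, i_lat = names.index("RAnkleMed"), names.index("RAnkleLat")
        mid = 0.5 * (pos[:, i_med] + pos[:, i_lat])
        clean_names, clean = generate_reference_markers(walking_truth, 0.0)
        mid0 = 0.5 * (clean[:, i_med] + clean[:, i_lat])
        err = (mid - mid0).std(axis=0)
        assert np.allclose(err, sd / np.sqrt(2), rtol=0.35)

    def test_mirrored_offset_sampling(self):
        off = sample_systematic_offsets(seed=1)
        r, l = np.asarray(off["RHip"]), np.asarray(off["LHip"])
        assert r[0] == l[0] and r[1] == l[1] and r[2] == -l[2]
        for v in off.values():
            assert 0.03 <= np.linalg.norm(v) <= 0.05
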