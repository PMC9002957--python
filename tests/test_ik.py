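import numpy as np
import pytest

from mvkin.ik import (
    DegenerateMotionError,
    SAGITTAL_ANGLES,
    ScalingError,
    compute_joint_angles,
    direct_segment_angles,
    functional_joint_center,
    inverse_kinematics_frame,
    inverse_kinematics_sequence,
    scale_model,
)
from mvkin.model import default_model
from mvkin.simulate import static_trial


def pose_with(model, **coords):
    q = np.zeros(len(model.free_dof_names))
    for name, val in coords.items():
        q[model.free_dof_names.index(name)] = val
    return q


class TestScaling:
    def test_simple_ratio(self, model):
        neutral = model.forward_kinematics(model.neutral_pose())
        # stretch the right thigh measurement by 10%
        kp = dict(neutral)
        hip, knee = kp["RHip"], kp["RKnee"]
        kp["RKnee"] = hip + 1.10 * (knee - hip)
        scaled, scales = scale_model(model, kp)
        assert scales["thigh_r"] == pytest.approx(1.10)

    def test_identity_when_measured_equals_model(self, model):
        neutral = model.forward_kinematics(model.neutral_pose())
        _, scales = scale_model(model, neutral)
        assert np.allclose(list(scales.values()), 1.0, atol=1e-12)

    def test_uniformly_scaled_subject_round_trip(self, model):
        truth = model.with_scales({s: 1.05 for s in model.segments})
        st = static_trial(truth, n_frames=1)
        kp = {n: st.keypoint_positions[0, i] for i, n in enumerate(st.keypoint_names)}
        _, scales = scale_model(default_model(), kp)
        assert np.allclose(list(scales.values()), 1.05, atol=1e-6)

    def test_missing_endpoint_names_the_pair(self, model):
        neutral = model.forward_kinematics(model.neutral_pose())
        del neutral["RKnee"]
        with pytest.raises(ScalingError, match="RKnee"):
            scale_model(model, neutral)


class TestIkFrame:
    def test_noiseless_round_trip(self, model):
        q_true = pose_with(
            model,
            pelvis_ty=0.95,
            pelvis_tilt=4.0,
            lumbar_flexion=8.0,
            hip_flexion_r=30.0,
            knee_flexion_r=40.0,
            ankle_flexion_r=-10.0,
            hip_adduction_r=5.0,
            hip_flexion_l=-10.0,
            knee_flexion_l=5.0,
            arm_flex_r=20.0,
            elbow_flex_r=30.0,
        )
        targets = model.forward_kinematics(q_true)
        pv = inverse_kinematics_frame(model, targets)
        assert pv.rmse < 1e-5
        assert np.allclose(pv.q, q_true, atol=0.1)

    def test_locks_are_exact_for_any_input(self, model):
        rng = np.random.default_rng(3)
        targets = {n: rng.normal(scale=0.5, size=3) + [0, 1, 0] for n in model.keypoints}
        pv = inverse_kinematics_frame(model, targets)
        values = model.resolve_coordinates(pv.q)
        assert values["pro_sup_r"] == 90.0
        assert values["pro_sup_l"] == 90.0
        assert values["wrist_flex_r"] == 0.0
        assert values["wrist_dev_l"] == 0.0

    def test_hip_flexion_clamped_at_150(self, model):
        # target pose demands 160 degrees (FK does not enforce limits)
        q_demand = pose_with(model, pelvis_ty=1.0, hip_flexion_r=160.0, knee_flexion_r=90.0)
        targets = model.forward_kinematics(q_demand)
        pv = inverse_kinematics_frame(model, targets)
        hip = pv.q[model.free_dof_names.index("hip_flexion_r")]
        assert hip <= 150.0 + 1e-9
        assert hip == pytest.approx(150.0, abs=0.5)
        assert pv.rmse > 0

    def test_limits_satisfied_on_random_targets(self, model):
        rng = np.random.default_rng(5)
        lo, hi = model.bounds_degrees()
        for _ in range(3):
            targets = {n: rng.normal(scale=0.6, size=3) + [0, 1, 0] for n in model.keypoints}
            pv = inverse_kinematics_frame(model, targets)
            assert np.all(pv.q >= lo - 1e-9) and np.all(pv.q <= hi + 1e-9)

    def test_too_few_valid_keypoints_invalid_frame(self, model):
        targets = {"RHip": np.array([0, 1, 0.1]), "LHip": np.array([0, 1, -0.1])}
        pv = inverse_kinematics_frame(model, targets)
        assert not pv.valid

    def test_objective_not_worse_than_start(self, model):
        rng = np.random.default_rng(11)
        q_true = pose_with(model, pelvis_ty=0.95, hip_flexion_r=40.0)
        targets = {
            n: p + rng.normal(scale=0.01, size=3)
            for n, p in model.forward_kinematics(q_true).items()
        }
        q0 = model.neutral_pose()
        pv = inverse_kinematics_frame(model, targets, q_init=q0)
        pv0 = inverse_kinematics_frame(model, targets, q_init=q0, max_iterations=1)
        assert pv.rmse <= pv0.rmse + 1e-12


class TestIkSequence:
    def test_noiseless_walking_round_trip(self, model, walking_truth, clean_trajectory):
        res = inverse_kinematics_sequence(model, clean_trajectory)
        assert res.rmse.max() < 1e-4
        ang = compute_joint_angles(model, res.q, which=SAGITTAL_ANGLES)
        for a in SAGITTAL_ANGLES:
            assert np.abs(ang[a] - walking_truth.angles[a]).max() < 0.5

    def test_warm_start_continuity(self, model, walking_truth, clean_trajectory):
        res = inverse_kinematics_sequence(model, clean_trajectory)
        jumps = np.abs(np.diff(res.q, axis=0)).max(axis=0)
        truth_jumps = np.abs(np.diff(walking_truth.q, axis=0)).max(axis=0)
        mask = truth_jumps > 0.1
        assert np.all(jumps[mask] <= 3.0 * truth_jumps[mask])

    def test_empty_trajectory_rejected(self, model):
        with pytest.raises(ValueError):
            inverse_kinematics_sequence(model, {"RHip": np.empty((0, 3))})


class TestFunctionalJointCenter:
    def test_exact_sphere_recovery(self):
        rng = np.random.default_rng(0)
        center = np.array([0.1, 0.9, 0.0])
        th = rng.uniform(0, np.pi, 60)
        ph = rng.uniform(0, 2 * np.pi, 60)
        pts = center + 0.3 * np.stack(
            [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)], axis=1
        )
        c, confident = functional_joint_center(pts[None])
        assert np.allclose(c, center, atol=1e-9)
        assert confident.all()

    def test_planar_arc_flags_out_of_plane_axis(self):
        th = np.linspace(0, 2 * np.pi, 80)
        pts = np.stack([0.2 * np.cos(th) + 0.1, 0.2 * np.sin(th) + 0.9, np.zeros_like(th)], axis=1)
        c, confident = functional_joint_center(pts[None])
        assert np.allclose(c[:2], [0.1, 0.9], atol=1e-6)
        assert not confident[2]

    def test_static_markers_degenerate(self):
        with pytest.raises(DegenerateMotionError):
            functional_joint_center(np.tile([0.1, 0.9, 0.0], (1, 20, 1)))

    def test_hip_center_recovered_from_rotating_cluster(self, model):
        """Markers rotating on a sphere about the hip recover its center."""
        rng = np.random.default_rng(2)
        free = model.free_dof_names
        cluster = [model.markers[f"RThigh{i}"][1] for i in range(1, 5)]
        hip_local = np.array([0.0, -0.07, 0.09])  # hip joint in pelvis frame
        trajs = []
        frames = []
        for _ in range(40):
            q = pose_with(
                model,
                hip_flexion_r=rng.uniform(-20, 60),
                hip_adduction_r=rng.uniform(-15, 15),
                hip_rotation_r=rng.uniform(-20, 20),
            )
            T = model.segment_transforms(q)
            R, p = T["thigh_r"]
            frames.append([p + R @ np.asarray(off) for off in cluster])
        M = np.array(frames).transpose(1, 0, 2)  # (markers, frames, 3)
        c, confident = functional_joint_center(M)
        assert np.allclose(c, hip_local, atol=1e-8)


class TestAngles:
    def test_constant_pose_gives_constant_signal(self, model):
        q = pose_with(model, hip_flexion_r=20.0)
        ang = compute_joint_angles(model, np.tile(q, (5, 1)), which=["hip_flexion_r"])
        assert np.allclose(ang["hip_flexion_r"], 20.0)

    def test_coupled_angles_follow_the_master(self, model):
        q = pose_with(model, knee_flexion_r=90.0)
        ang = compute_joint_angles(
            model, np.tile(q, (3, 1)), which=["knee_adduction_r", "knee_rotation_r"]
        )
        assert np.allclose(ang["knee_adduction_r"], 3.0)
        assert np.allclose(ang["knee_rotation_r"], 8.0)

    def test_unknown_angle_name_rejected(self, model):
        with pytest.raises(KeyError):
            compute_joint_angles(model, np.zeros((2, len(model.free_dof_names))), which=["spine_wobble"])

    def test_direct_angles_match_truth_on_clean_sagittal_pose(self, model):
        # pure sagittal walking pose: segment-vector angles equal coordinates
        q = pose_with(model, pelvis_ty=0.95, hip_flexion_r=25.0, knee_flexion_r=35.0)
        kp = model.forward_kinematics(q)
        names = list(kp)
        P = np.array([kp[n] for n in names])[None]
        ang = direct_segment_angles(P, names)
        assert ang["hip_flexion_r"][0] == pytest.approx(25.0, abs=1.5)
        assert ang["knee_flexion_r"][0] == pytest.approx(35.0, abs=1.5)
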