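"""End-to-end pipeline: triangulate -> filter -> events -> scale -> IK -> agree.

Two entry points:

* :func:`run_pipeline` — the file-based command used by the CLI: reads
  OpenPose-dialect JSON and a rig TOML, writes TRC/MOT/CSV outputs and a
  log sufficient to replay the configuration;
* :func:`run_synthetic_experiment` — the in-memory variant that generates a
  virtual-camera trial, runs the same stages, and also solves the parallel
  marker-based reference channel, returning everything (including ground
  truth) for validation studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from mvkin import cameras
from mvkin.config import PipelineConfig
from mvkin.ik import (
    IkResult,
    LOWER_LIMB_ANGLES,
    compute_joint_angles,
    direct_segment_angles,
    functional_joint_center,
    inverse_kinematics_frame,
    inverse_kinematics_sequence,
    scale_model,
)
from mvkin.model import DEFAULT_STATIC_PRIORS, SkeletalModel, default_model
from mvkin.simulate import (
    CorruptionSpec,
    GroundTruth,
    LANDMARK_PAIRS,
    MotionSpec,
    generate_motion,
    generate_reference_markers,
    observe,
    static_trial,
)
from mvkin.timeseries import (
    CycleSet,
    FilterSpec,
    build_cycles,
    butterworth_lowpass,
    detect_heel_strikes,
    detect_vertical_peaks,
)
from mvkin.triangulate import Trajectory3D, triangulate_sequence
from mvkin import agreement as agr
from mvkin import io as mio

log = logging.getLogger("mvkin")

__all__ = ["run_pipeline", "run_synthetic_experiment", "PipelineError", "ExperimentResult"]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _filter_trajectory(traj: Trajectory3D, spec: FilterSpec) -> Trajectory3D:
    """Low-pass each keypoint column; invalid interior samples are bridged
    by linear interpolation before filtering so the filter sees no NaNs, and
    stay flagged invalid afterwards."""
    P = traj.positions.copy()
    F, K, _ = P.shape
    for k in range(K):
        v = traj.valid[:, k]
        if not v.any():
            continue
        idx = np.arange(F)
        for a in range(3):
            col = P[:, k, a]
            if not v.all():
                col = np.interp(idx, idx[v], col[v])
            P[:, k, a] = col
        P[:, k] = butterworth_lowpass(P[:, k], spec)
    return Trajectory3D(
        P,
        traj.valid.copy(),
        traj.n_cameras_used.copy(),
        traj.reproj_error.copy(),
        list(traj.keypoint_names),
        traj.frame_rate,
        traj.low_quality.copy(),
        traj.interpolated.copy(),
    )


def _detect_events(
    traj: Trajectory3D, task: str, cadence: float, progression_axis: int = 0,
    vertical_axis: int = 1, direction: float | None = None,
) -> np.ndarray:
    names = traj.keypoint_names
    pos = traj.positions
    idx = {n: i for i, n in enumerate(names)}
    if task == "cycling":
        return detect_vertical_peaks(
            pos[:, idx["RAnkle"]], vertical_axis, cadence, traj.frame_rate
        )
    sacrum = 0.5 * (pos[:, idx["RHip"]] + pos[:, idx["LHip"]])
    if direction is None:
        # per-frame direction of travel (handles back-and-forth passes):
        # sign of the smoothed progression velocity of the sacrum
        x = sacrum[:, progression_axis]
        v = np.gradient(x)
        win = max(3, int(round(0.3 * traj.frame_rate)) | 1)
        kernel = np.ones(win) / win
        v = np.convolve(v, kernel, mode="same")
        if np.ptp(x) < 0.5:
            direction = 1.0  # stationary subject (treadmill-like trials)
        else:
            direction = np.where(v >= 0, 1.0, -1.0)
    return detect_heel_strikes(
        pos[:, idx["RHeel"]],
        sacrum,
        progression_axis,
        direction,
        cadence,
        traj.frame_rate,
    )


def _reference_joint_centers(truth: GroundTruth, soft_tissue_sd: float, seed: int) -> dict:
    """Marker-based channel: joint centers from the anatomical markers.

    Ankle/knee/wrist centers are landmark-pair midpoints; the hip center is
    recovered with the functional (sphere-fit) method from the thigh cluster
    expressed in the pelvis frame; the sacrum, heel and toe markers are kept
    as direct targets.
    """
    names, pos = generate_reference_markers(truth, soft_tissue_sd, seed)
    idx = {n: i for i, n in enumerate(names)}
    targets: dict[str, np.ndarray] = {}
    for joint, (a, b) in LANDMARK_PAIRS.items():
        targets[joint] = 0.5 * (pos[:, idx[a]] + pos[:, idx[b]])
    for direct in ("Sacrum", "RHeel", "LHeel", "RToe", "LToe"):
        if direct in idx:
            targets[direct] = pos[:, idx[direct]]
    # functional hip center per side, expressed in the pelvis frame of the
    # generating model, then mapped back per frame
    F = pos.shape[0]
    pelvis_R = _pelvis_rotations(truth)
    for side, S in (("r", "R"), ("l", "L")):
        cluster = [f"{S}Thigh{i}" for i in range(1, 5)]
        origin = truth.marker_positions[:, truth.marker_names.index("Sacrum")]
        local = np.empty((len(cluster), F, 3))
        for m, name in enumerate(cluster):
            world = pos[:, idx[name]]
            local[m] = np.einsum("fba,fb->fa", pelvis_R, world - origin)
        center_local, _ = functional_joint_center(local)
        targets[f"{S}Hip"] = origin + np.einsum("fab,b->fa", pelvis_R, center_local)
    return targets


def _pelvis_rotations(truth: GroundTruth) -> np.ndarray:
    """Per-frame world rotation of the pelvis segment of the ground truth."""
    F = truth.q.shape[0]
    out = np.empty((F, 3, 3))
    model = truth.model
    for f in range(F):
        out[f] = model.segment_transforms(truth.q[f])["pelvis"][0]
    return out


@dataclass
class ExperimentResult:
    """Everything a validation study needs from one synthetic trial."""

    truth: GroundTruth
    trajectory: Trajectory3D
    filtered: Trajectory3D
    events: np.ndarray
    cycles: CycleSet | None
    scales: dict
    ik: IkResult
    angles: dict  # markerless channel, name -> (F,) degrees
    direct_angles: dict  # model-free segment-vector baseline
    reference_ik: IkResult | None = None
    reference_angles: dict | None = None
    agreement_table: object | None = None


def run_synthetic_experiment(
    spec: MotionSpec | None = None,
    corrupt: CorruptionSpec | None = None,
    model: SkeletalModel | None = None,
    n_cameras: int = 8,
    rig_radius: float = 4.0,
    min_confidence: float = 0.3,
    max_reproj_error: float = 15.0,
    filter_spec: FilterSpec | None = None,
    with_reference: bool = False,
    soft_tissue_sd: float = 0.0,
    normalized_length: int = 101,
    ik_tol: float = 1e-8,
) -> ExperimentResult:
    """Generate a virtual trial and run the full markerless pipeline on it.

    When ``with_reference`` is set, the marker-based channel is also solved
    (IK on joint centers computed from the simulated anatomical markers) and
    the agreement table between the two channels is produced.
    """
    spec = spec or MotionSpec()
    corrupt = corrupt or CorruptionSpec()
    model = model if model is not None else default_model()

    truth = generate_motion(spec, model)
    rig = cameras.make_rig(n_cameras, rig_radius)
    obs = observe(truth, rig, corrupt)
    traj = triangulate_sequence(obs, rig, max_reproj_error, min_confidence)

    fspec = filter_spec or FilterSpec(sample_rate=spec.frame_rate)
    filtered = _filter_trajectory(traj, fspec)

    events = _detect_events(filtered, spec.task, spec.cadence)
    cycles = build_cycles(events, normalized_length, truth.direction_per_cycle) if len(events) >= 2 else None

    # measurement-based scaling from a static trial seen by the same rig
    static = static_trial(model)
    static_obs = observe(static, rig, corrupt)
    static_traj = triangulate_sequence(static_obs, rig, max_reproj_error, min_confidence)
    static_kp = {
        n: np.nanmean(static_traj.positions[:, k], axis=0)
        for k, n in enumerate(static_traj.keypoint_names)
    }
    unscaled = default_model()
    scaled, scales = scale_model(unscaled, static_kp)

    # static pose solve with the zero-angle priors refines nothing here but
    # validates the scaled model against the static detections
    ik = inverse_kinematics_sequence(scaled, filtered, tol=ik_tol)
    angles = compute_joint_angles(scaled, ik.q, which=LOWER_LIMB_ANGLES)
    direct = direct_segment_angles(filtered.positions, filtered.keypoint_names)

    ref_ik = None
    ref_angles = None
    table = None
    if with_reference:
        ref_targets = _reference_joint_centers(truth, soft_tissue_sd, corrupt.seed + 1)
        ref_targets = {
            n: butterworth_lowpass(p, fspec) for n, p in ref_targets.items()
        }
        ref_weights = {n: 5.0 for n in ref_targets}
        for anatomical in ("Sacrum", "RHeel", "LHeel", "RToe", "LToe"):
            ref_weights[anatomical] = 2.0
        ref_ik = inverse_kinematics_sequence(
            scaled, ref_targets, weights=ref_weights, frame_rate=spec.frame_rate, tol=ik_tol
        )
        ref_angles = compute_joint_angles(scaled, ref_ik.q, which=LOWER_LIMB_ANGLES)
        if cycles is not None:
            table = agr.summarize(angles, ref_angles, cycles, task=spec.task)

    return ExperimentResult(
        truth=truth,
        trajectory=traj,
        filtered=filtered,
        events=events,
        cycles=cycles,
        scales=scales,
        ik=ik,
        angles=angles,
        direct_angles=direct,
        reference_ik=ref_ik,
        reference_angles=ref_angles,
        agreement_table=table,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """File-based pipeline: reads detections + rig, writes the output bundle.

    Returns a dict of output paths.  Stage failures raise
    :class:`PipelineError` naming the stage; outputs produced by earlier
    stages are left on disk.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    outputs: dict[str, str] = {"log": str(out_dir / "pipeline.log")}
    mio.save_toml(out_dir / "config_used.toml", config.to_dict())
    outputs["config"] = str(out_dir / "config_used.toml")
    log.info("config: %s", config.to_dict())

    try:
        rig = cameras.rig_from_dict(mio.load_toml(config.rig_file))
        obs = mio.read_openpose_json(config.pose_dir)
        log.info(
            "read %d frames x %d cameras x %d keypoints",
            obs.n_frames, obs.n_cameras, len(obs.keypoint_names),
        )
    except Exception as e:
        raise PipelineError("read", str(e)) from e

    tc = config.triangulation
    try:
        traj = triangulate_sequence(
            obs, rig, tc.max_reproj_error, tc.min_confidence, tc.max_gap
        )
        n_excluded = int(np.sum(obs.n_cameras - traj.n_cameras_used[traj.valid]))
        log.info(
            "triangulated: %.1f%% valid samples, mean residual %.2f px, "
            "%d camera-observations excluded",
            100.0 * traj.valid.mean(),
            float(np.nanmean(traj.reproj_error)),
            n_excluded,
        )
        mio.write_trc(out_dir / "triangulated.trc", traj.keypoint_names, traj.positions, traj.frame_rate)
        mio.write_trajectory_quality(out_dir / "quality.csv", traj)
        outputs["trc"] = str(out_dir / "triangulated.trc")
        outputs["quality"] = str(out_dir / "quality.csv")
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("triangulate", str(e)) from e

    fc = config.filter
    try:
        fspec = FilterSpec(fc.order, fc.cutoff, traj.frame_rate, fc.zero_phase)
        filtered = _filter_trajectory(traj, fspec)
        log.info("filtered with order-%d %g Hz Butterworth (zero_phase=%s)",
                 fc.order, fc.cutoff, fc.zero_phase)
        mio.write_trc(out_dir / "filtered.trc", filtered.keypoint_names, filtered.positions, filtered.frame_rate)
        outputs["filtered_trc"] = str(out_dir / "filtered.trc")
    except Exception as e:
        raise PipelineError("filter", str(e)) from e

    ec = config.events
    try:
        events = _detect_events(
            filtered, ec.task, ec.cadence, ec.progression_axis, ec.vertical_axis
        )
        cycles = build_cycles(events, config.agreement.normalized_length)
        log.info("detected %d events -> %d cycles", len(events), len(cycles.cycles))
        mio.write_cycles_csv(out_dir / "cycles.csv", cycles)
        outputs["cycles"] = str(out_dir / "cycles.csv")
    except Exception as e:
        raise PipelineError("events", str(e)) from e

    try:
        model = (
            SkeletalModel.from_dict(mio.load_toml(config.model_file))
            if config.model_file
            else default_model()
        )
        if config.ik.keypoint_offsets:
            model = model.with_keypoint_offsets(
                {k: tuple(v) for k, v in config.ik.keypoint_offsets.items()}
            )
        if config.static_pose_dir:
            sobs = mio.read_openpose_json(config.static_pose_dir)
            straj = triangulate_sequence(sobs, rig, tc.max_reproj_error, tc.min_confidence)
            static_kp = {
                n: np.nanmean(straj.positions[:, k], axis=0)
                for k, n in enumerate(straj.keypoint_names)
            }
            model, scales = scale_model(model, static_kp)
            # static-pose IK with the zero-angle stance priors, reported for QC
            pv = inverse_kinematics_frame(
                model, static_kp, static_priors=DEFAULT_STATIC_PRIORS
            )
            log.info("scaling: factors %s; static-fit RMSE %.4f m", scales, pv.rmse)
        else:
            scales = dict(model.scales)
            log.info("no static trial configured: scale factors left at 1")
        mio.save_toml(out_dir / "scaled_model.toml", model.to_dict())
        outputs["model"] = str(out_dir / "scaled_model.toml")
    except Exception as e:
        raise PipelineError("scale", str(e)) from e

    try:
        ik = inverse_kinematics_sequence(
            model, filtered, max_iterations=config.ik.max_iterations, tol=config.ik.tol
        )
        angles = compute_joint_angles(model, ik.q, which=LOWER_LIMB_ANGLES)
        log.info(
            "IK: marker RMSE %.4f-%.4f m (best practice: < 0.02-0.04 m)",
            float(np.nanmin(ik.rmse)),
            float(np.nanmax(ik.rmse)),
        )
        mio.write_mot(out_dir / "angles.mot", angles, traj.frame_rate)
        import pandas as pd

        pd.DataFrame({"frame": np.arange(len(ik.rmse)), "rmse_m": ik.rmse}).to_csv(
            out_dir / "ik_rmse.csv", index=False
        )
        outputs["mot"] = str(out_dir / "angles.mot")
        outputs["ik_rmse"] = str(out_dir / "ik_rmse.csv")
    except Exception as e:
        raise PipelineError("ik", str(e)) from e

    if config.reference_trc:
        try:
            ref_names, ref_pos, ref_rate = mio.read_trc(config.reference_trc)
            ref_targets = {n: ref_pos[:, i] for i, n in enumerate(ref_names)}
            ref_ik = inverse_kinematics_sequence(model, ref_targets, frame_rate=ref_rate)
            ref_angles = compute_joint_angles(model, ref_ik.q, which=LOWER_LIMB_ANGLES)
            table = agr.summarize(angles, ref_angles, cycles, task=ec.task)
            table.to_csv(out_dir / "agreement.csv", index=False)
            outputs["agreement"] = str(out_dir / "agreement.csv")
            log.info("agreement table written (%d angles)", len(table))
        except Exception as e:
            raise PipelineError("agree", str(e)) from e

    log.removeHandler(handler)
    handler.close()
    return outputs
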