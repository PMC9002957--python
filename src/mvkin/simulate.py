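"""Synthetic multi-camera gait experiments with known ground truth.

The simulator emulates the study conditions of a virtual-camera concurrent
validation: a subject walking, running, or pedaling at a metronome-driven
cadence, filmed by an 8-camera virtual rig at 30 Hz, with the 2D keypoint
detections corrupted by Gaussian pixel noise, constant per-keypoint 3D
offsets (the systematic joint-center bias of deep-learning pose estimators,
up to 5 cm at the hip and knee), and per-camera occlusion dropouts.  A
parallel marker-based reference channel emits anatomical-landmark
trajectories whose midpoints are the true joint centers.

Joint-angle trajectories are sums of at most three harmonics of the cadence,
so they are band-limited well below the 6 Hz filter cutoff, plus a slow
seeded amplitude modulation (default 2%) so consecutive cycles are similar
but not identical, as in real gait.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from mvkin.cameras import CameraParams, in_image, project_points
from mvkin.model import SkeletalModel, default_model
from mvkin.triangulate import KeypointObservationSet

__all__ = [
    "MotionSpec",
    "CorruptionSpec",
    "GroundTruth",
    "GenerationError",
    "generate_motion",
    "static_trial",
    "observe",
    "generate_reference_markers",
    "TASK_TABLES",
]

#: Fraction of a cycle by which the waveforms are delayed so that the first
#: heel strike falls a few frames into the trial instead of on frame 0.
EVENT_PHASE = 0.1


class GenerationError(ValueError):
    """Raised when a motion specification is infeasible for the model."""


def offset_reference_segment(model: SkeletalModel, keypoint: str) -> str:
    """Segment whose frame a keypoint's systematic offset is constant in.

    A joint-center keypoint (placed at its segment's origin) is a landmark
    of the *proximal* body region — a pose detector mislocalizes the hip
    relative to the pelvis, not relative to the swinging thigh — so its
    offset is expressed in the parent segment's frame.  Keypoints placed
    away from the joint (heel, toes, head) use their own segment.
    """
    seg_name, local = model.keypoints[keypoint]
    seg = model.segments[seg_name]
    if seg.parent is not None and float(np.linalg.norm(local)) < 1e-12:
        return seg.parent
    return seg_name


@dataclass(frozen=True)
class MotionSpec:
    """Periodic task description: what the subject does and how fast.

    ``cadence`` is the metronome frequency in Hz (cycles per second); stride
    duration is its inverse.  ``angle_amplitudes`` / ``angle_offsets``
    override the fundamental amplitude / constant offset (degrees) of
    individual DOFs on top of the task's default table.
    """

    task: str = "walking"
    cadence: float = 1.0
    n_cycles: int = 8
    frame_rate: float = 30.0
    angle_amplitudes: dict = field(default_factory=dict)
    angle_offsets: dict = field(default_factory=dict)
    stride_length: float | None = None  # meters; None = task default
    cycle_variability: float = 0.02  # relative slow amplitude modulation
    # back-and-forth protocol: cycles per pass before turning around
    # (0 = single pass; None = task default, 2 for gait tasks)
    reversal_every: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in TASK_TABLES:
            raise GenerationError(f"unknown task {self.task!r}")
        if self.n_cycles < 1:
            raise GenerationError("n_cycles must be >= 1")
        if self.frame_rate <= 2.0 * self.cadence:
            raise GenerationError("frame_rate must exceed twice the cadence")
        if any(a < 0 for a in self.angle_amplitudes.values()):
            raise GenerationError("amplitudes must be nonnegative")


@dataclass(frozen=True)
class CorruptionSpec:
    """Observation-corruption model for the virtual detector.

    ``systematic_offsets`` maps keypoint names to constant 3D offsets
    (meters) applied before projection; by default they are expressed in the
    keypoint's segment-local frame so the bias travels with the limb
    (``offset_frame='world'`` keeps them world-fixed).  Visible keypoints get
    confidence ``clamp(1 - pixel_error / confidence_scale_px, 0, 1)``;
    occluded ones get 0.
    """

    pixel_noise_sd: float = 0.0
    systematic_offsets: dict = field(default_factory=dict)
    offset_frame: str = "local"  # 'local' | 'world'
    occlusions: list = field(default_factory=list)  # (cam, keypoint|'*', start, stop)
    confidence_scale_px: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_noise_sd < 0:
            raise ValueError("pixel_noise_sd must be >= 0")
        if self.offset_frame not in ("local", "world"):
            raise ValueError("offset_frame must be 'local' or 'world'")
        for name, off in self.systematic_offsets.items():
            if np.linalg.norm(np.asarray(off, float)) > 0.1:
                raise ValueError(
                    f"systematic offset for {name!r} exceeds the 0.1 m bound"
                )


@dataclass
class GroundTruth:
    """The simulator's oracle channel: everything downstream must recover."""

    frame_rate: float
    times: np.ndarray  # (F,)
    coord_names: list  # free-DOF order of q
    q: np.ndarray  # (F, n_free) degrees / meters
    angles: dict  # full coordinate name -> (F,) degrees (locked/coupled too)
    keypoint_names: list
    keypoint_positions: np.ndarray  # (F, K, 3) meters
    keypoint_rotations: np.ndarray  # (F, K, 3, 3) parent-segment world rotation
    marker_names: list
    marker_positions: np.ndarray  # (F, M, 3) meters
    event_frames: np.ndarray  # right-heel-strike frame indices (cycle starts)
    direction_per_cycle: np.ndarray  # progression-axis sign of each cycle
    task: str
    cadence: float
    model: SkeletalModel


def _h(amp, phase, harmonic=1):
    return (harmonic, amp, phase)


# Per-task waveform tables: dof -> (offset_deg, [(harmonic, amplitude, phase)]).
# Phases are cycle fractions; phase 0 peaks at the heel strike of the
# right leg.  Left-side DOFs are the same curves shifted by half a cycle.
# Amplitudes are conservative textbook-order values for each task.
def _leg_table(hip_off, hip_amp, knee_off, knee_amp, ankle_amp):
    return {
        "hip_flexion": (hip_off, [_h(hip_amp, 0.0)]),
        "knee_flexion": (knee_off, [_h(-knee_amp, 0.0), _h(0.15 * knee_amp, 0.1, 2)]),
        "ankle_flexion": (0.0, [_h(ankle_amp, 0.25)]),
        "hip_adduction": (0.0, [_h(5.0, 0.15)]),
        "hip_rotation": (0.0, [_h(4.0, 0.3)]),
        "subtalar": (0.0, [_h(4.0, 0.2)]),
    }


TASK_TABLES: dict[str, dict] = {
    "walking": {
        "stride_length": 1.3,
        "cadence": 1.0,
        "legs": _leg_table(10.0, 25.0, 33.0, 27.0, 12.0),
        "trunk": {
            "pelvis_tilt": (3.0, [_h(1.5, 0.05, 2)]),
            "pelvis_list": (0.0, [_h(2.0, 0.0)]),
            "pelvis_rotation": (0.0, [_h(5.0, 0.0)]),
            "lumbar_flexion": (5.0, [_h(3.0, 0.1, 2)]),
            "pelvis_ty": (0.95, [_h(0.02, 0.05, 2)]),
        },
        "arms": {
            "arm_flex": (0.0, [_h(15.0, 0.5)]),
            "arm_add": (-8.0, []),
            "elbow_flex": (20.0, [_h(5.0, 0.5)]),
        },
    },
    "running": {
        "stride_length": 2.0,
        "cadence": 1.3,
        "legs": _leg_table(20.0, 35.0, 62.0, 50.0, 18.0),
        "trunk": {
            "pelvis_tilt": (6.0, [_h(2.0, 0.05, 2)]),
            "pelvis_list": (0.0, [_h(3.0, 0.0)]),
            "pelvis_rotation": (0.0, [_h(7.0, 0.0)]),
            "lumbar_flexion": (8.0, [_h(4.0, 0.1, 2)]),
            "pelvis_ty": (0.96, [_h(0.04, 0.05, 2)]),
        },
        "arms": {
            "arm_flex": (10.0, [_h(25.0, 0.5)]),
            "arm_add": (-8.0, []),
            "elbow_flex": (70.0, [_h(10.0, 0.5)]),
        },
    },
    # Seated pedaling: no progression, large hip/knee flexion, cycles
    # segmented by the vertical excursion of the ankle rather than by heel
    # strikes.
    "cycling": {
        "stride_length": 0.0,
        "cadence": 1.2,
        "legs": {
            "hip_flexion": (65.0, [_h(20.0, 0.0)]),
            "knee_flexion": (75.0, [_h(35.0, 0.05)]),
            "ankle_flexion": (0.0, [_h(15.0, 0.15)]),
            "hip_adduction": (0.0, [_h(3.0, 0.15)]),
            "hip_rotation": (0.0, [_h(3.0, 0.3)]),
            "subtalar": (0.0, [_h(4.0, 0.2)]),
        },
        "trunk": {
            "pelvis_tilt": (20.0, [_h(1.0, 0.05, 2)]),
            "pelvis_list": (0.0, [_h(1.5, 0.0)]),
            "pelvis_rotation": (0.0, [_h(2.0, 0.0)]),
            "lumbar_flexion": (25.0, [_h(2.0, 0.1, 2)]),
            "pelvis_ty": (1.0, [_h(0.01, 0.05, 2)]),
        },
        "arms": {
            "arm_flex": (70.0, []),
            "arm_add": (-5.0, []),
            "elbow_flex": (25.0, []),
        },
    },
}


def _dof_waveforms(spec: MotionSpec) -> dict[str, tuple[float, list]]:
    """Expand the task table into per-DOF (offset, harmonics) entries."""
    table = TASK_TABLES[spec.task]
    out: dict[str, tuple[float, list]] = {}
    for name, (off, harms) in table["trunk"].items():
        out[name] = (off, [(h, a, p) for h, a, p in harms])
    for side, shift in (("r", 0.0), ("l", 0.5)):
        for base, (off, harms) in table["legs"].items():
            out[f"{base}_{side}"] = (off, [(h, a, p + shift * h) for h, a, p in harms])
        for base, (off, harms) in table["arms"].items():
            out[f"{base}_{side}"] = (off, [(h, a, p + shift * h) for h, a, p in harms])
    # a user amplitude replaces the DOF's harmonics with a single fundamental
    # of that amplitude (keeping the default's sign and phase), so the
    # trajectory stays within offset +/- amplitude exactly
    for name, amp in spec.angle_amplitudes.items():
        off, harms = out.get(name, (0.0, [(1, 0.0, 0.0)]))
        if not harms:
            harms = [(1, 0.0, 0.0)]
        h0, a0, p0 = harms[0]
        out[name] = (off, [(h0, math.copysign(amp, a0) if a0 else amp, p0)])
    for name, off in spec.angle_offsets.items():
        _, harms = out.get(name, (0.0, []))
        out[name] = (off, harms)
    return out


def generate_motion(spec: MotionSpec, model: SkeletalModel | None = None) -> GroundTruth:
    """Generate a ground-truth trial: angles, keypoints, markers, events.

    Deterministic given ``spec.seed``.  Raises :class:`GenerationError` when
    a requested amplitude would push a DOF past the model's limits.
    """
    model = model if model is not None else default_model()
    rng = np.random.default_rng(spec.seed)
    fs, cad = spec.frame_rate, spec.cadence
    frames_per_cycle = fs / cad
    n_frames = int(round(spec.n_cycles * frames_per_cycle))
    t = np.arange(n_frames) / fs
    phase = cad * t - EVENT_PHASE  # cycle coordinate; heel strike at integers

    waveforms = _dof_waveforms(spec)
    free = model.free_dof_names
    jit = spec.cycle_variability

    # feasibility check against the model's limits
    for name, (off, harms) in waveforms.items():
        if name not in free:
            continue
        d = model.dof(name)
        span = sum(abs(a) for _, a, _ in harms) * (1.0 + jit)
        if off - span < d.bounds[0] - 1e-9 or off + span > d.bounds[1] + 1e-9:
            raise GenerationError(
                f"amplitude for DOF {name!r} exceeds its limits "
                f"[{d.bounds[0]}, {d.bounds[1]}]"
            )

    # slow seeded amplitude modulation -> cycles similar but not identical
    def modulation(name: str) -> np.ndarray:
        if jit == 0.0:
            return np.ones(n_frames)
        p1, p2 = rng.uniform(0, 2 * math.pi, size=2)
        s = 0.5 * np.sin(2 * math.pi * 0.21 * cad * t + p1)
        s += 0.5 * np.sin(2 * math.pi * 0.34 * cad * t + p2)
        return 1.0 + jit * s

    q = np.zeros((n_frames, len(free)))
    index = {name: i for i, name in enumerate(free)}
    for name, (off, harms) in waveforms.items():
        if name not in index:
            continue
        sig = np.full(n_frames, float(off))
        mod = modulation(name)
        for h, amp, ph in harms:
            sig = sig + amp * mod * np.cos(2 * math.pi * h * (phase - ph))
        q[:, index[name]] = sig

    # progression: back-and-forth passes with smooth turns.  The walking
    # volume is limited, so the subject walks a few cycles one way, turns
    # around (smooth 180 deg yaw plus a velocity ramp over half a cycle,
    # centered mid-swing so heel strikes stay clean), and walks back.
    stride = TASK_TABLES[spec.task]["stride_length"]
    if spec.stride_length is not None:
        stride = spec.stride_length
    speed = stride * cad
    reversal = spec.reversal_every
    if reversal is None:
        reversal = 2 if stride > 0 else 0
    direction = np.ones(spec.n_cycles)
    s = np.ones(n_frames)  # smooth per-frame direction in [-1, 1]
    if reversal > 0 and stride > 0:
        passes = np.arange(spec.n_cycles) // reversal
        direction = np.where(passes % 2 == 0, 1.0, -1.0)
        half = max(1, int(round(0.25 * frames_per_cycle)))
        frame_idx = np.arange(n_frames)
        n_turns = (spec.n_cycles - 1) // reversal
        for k in range(1, n_turns + 1):
            # turn centered half a cycle before the new pass's heel strike
            center = (k * reversal - 0.5 + EVENT_PHASE) * frames_per_cycle
            lo, hi = center - half, center + half
            before = 1.0 if (k - 1) % 2 == 0 else -1.0
            s[frame_idx > hi] = -before
            band = (frame_idx >= lo) & (frame_idx <= hi)
            s[band] = before * np.cos(0.5 * math.pi * (frame_idx[band] - lo) / half)
    v = s * speed
    x = np.concatenate([[0.0], np.cumsum(v[:-1]) / fs])
    x -= 0.5 * (x.max() + x.min())  # center the excursion in the volume
    q[:, index["pelvis_tx"]] = x
    q[:, index["pelvis_rotation"]] += 90.0 * (1.0 - s)

    # forward kinematics sweep
    kp_names = list(model.keypoints)
    mk_names = list(model.markers)
    kp_seg = [model.keypoints[k][0] for k in kp_names]
    kp_ref = [offset_reference_segment(model, k) for k in kp_names]
    kp_pos = np.empty((n_frames, len(kp_names), 3))
    kp_rot = np.empty((n_frames, len(kp_names), 3, 3))
    mk_pos = np.empty((n_frames, len(mk_names), 3))
    for f in range(n_frames):
        T = model.segment_transforms(q[f])
        for j, (name, seg) in enumerate(zip(kp_names, kp_seg)):
            R, p = T[seg]
            off = model.scales[seg] * np.asarray(model.keypoints[name][1])
            kp_pos[f, j] = p + R @ off
            kp_rot[f, j] = T[kp_ref[j]][0]
        for j, name in enumerate(mk_names):
            seg, off = model.markers[name]
            R, p = T[seg]
            mk_pos[f, j] = p + R @ (model.scales[seg] * np.asarray(off))

    events = np.round((np.arange(spec.n_cycles) + EVENT_PHASE) * frames_per_cycle)
    events = events[events < n_frames].astype(int)

    angles = {}
    for f_idx, name in enumerate(free):
        angles[name] = q[:, f_idx].copy()
    # resolve locked / coupled coordinates for the oracle channel
    for d in model.dofs:
        if d.kind == "locked":
            angles[d.name] = np.full(n_frames, d.value)
    for d in model.dofs:
        if d.kind == "coupled":
            master = angles[d.master]
            angles[d.name] = np.array([d.coupled_value(m) for m in master])

    return GroundTruth(
        frame_rate=fs,
        times=t,
        coord_names=free,
        q=q,
        angles=angles,
        keypoint_names=kp_names,
        keypoint_positions=kp_pos,
        keypoint_rotations=kp_rot,
        marker_names=mk_names,
        marker_positions=mk_pos,
        event_frames=events,
        direction_per_cycle=direction,
        task=spec.task,
        cadence=cad,
        model=model,
    )


def static_trial(
    model: SkeletalModel | None = None,
    n_frames: int = 10,
    frame_rate: float = 30.0,
    pose: dict | None = None,
) -> GroundTruth:
    """A stationary T-pose trial used for measurement-based scaling."""
    model = model if model is not None else default_model()
    free = model.free_dof_names
    qs = np.zeros(len(free))
    tpose = {"pelvis_ty": 0.95, "arm_add_r": -90.0, "arm_add_l": 90.0}
    tpose.update(pose or {})
    for name, val in tpose.items():
        qs[free.index(name)] = val
    n = n_frames
    kp_names = list(model.keypoints)
    T = model.segment_transforms(qs)
    kp_pos = np.empty((n, len(kp_names), 3))
    kp_rot = np.empty((n, len(kp_names), 3, 3))
    for j, name in enumerate(kp_names):
        seg, off = model.keypoints[name]
        R, p = T[seg]
        kp_pos[:, j] = p + R @ (model.scales[seg] * np.asarray(off))
        kp_rot[:, j] = T[offset_reference_segment(model, name)][0]
    mk_names = list(model.markers)
    mk_pos = np.empty((n, len(mk_names), 3))
    for j, name in enumerate(mk_names):
        seg, off = model.markers[name]
        R, p = T[seg]
        mk_pos[:, j] = p + R @ (model.scales[seg] * np.asarray(off))
    angles = {name: np.full(n, qs[i]) for i, name in enumerate(free)}
    return GroundTruth(
        frame_rate=frame_rate,
        times=np.arange(n) / frame_rate,
        coord_names=free,
        q=np.tile(qs, (n, 1)),
        angles=angles,
        keypoint_names=kp_names,
        keypoint_positions=kp_pos,
        keypoint_rotations=kp_rot,
        marker_names=mk_names,
        marker_positions=mk_pos,
        event_frames=np.array([], dtype=int),
        direction_per_cycle=np.array([1.0]),
        task="static",
        cadence=0.0,
        model=model,
    )


def observe(
    truth: GroundTruth,
    rig: list[CameraParams],
    corrupt: CorruptionSpec | None = None,
) -> KeypointObservationSet:
    """Render the ground truth into noisy per-camera 2D observations.

    Each keypoint is first displaced by its constant systematic 3D offset,
    then projected into every camera, then perturbed by Gaussian pixel noise.
    Confidence encodes the realized pixel error through the inverse-linear
    model; occluded or out-of-view keypoints get confidence 0.  Deterministic
    given ``corrupt.seed``.
    """
    corrupt = corrupt or CorruptionSpec()
    rng = np.random.default_rng(corrupt.seed)
    F, K = truth.keypoint_positions.shape[:2]
    C = len(rig)
    if C == 0:
        return KeypointObservationSet(
            np.zeros((F, 0, K, 3)), list(truth.keypoint_names), truth.frame_rate
        )

    pts = truth.keypoint_positions.copy()
    for name, off in corrupt.systematic_offsets.items():
        if name not in truth.keypoint_names:
            continue
        j = truth.keypoint_names.index(name)
        off = np.asarray(off, dtype=float)
        if corrupt.offset_frame == "world":
            pts[:, j] += off
        else:
            pts[:, j] += np.einsum("fab,b->fa", truth.keypoint_rotations[:, j], off)

    occluded = np.zeros((F, C, K), dtype=bool)
    for cam_i, kp, start, stop in corrupt.occlusions:
        cols = range(K) if kp == "*" else [truth.keypoint_names.index(kp)]
        for j in cols:
            occluded[start:stop, cam_i, j] = True

    uvc = np.zeros((F, C, K, 3))
    flat = pts.reshape(-1, 3)
    for c, cam in enumerate(rig):
        uv, in_front = project_points(flat, cam)
        visible = in_front & in_image(uv, cam)
        uv = uv.reshape(F, K, 2)
        visible = visible.reshape(F, K) & ~occluded[:, c]
        noise = rng.normal(0.0, corrupt.pixel_noise_sd or 0.0, size=(F, K, 2))
        if corrupt.pixel_noise_sd == 0.0:
            noise = np.zeros((F, K, 2))
        err = np.linalg.norm(noise, axis=-1)
        conf = np.clip(1.0 - err / corrupt.confidence_scale_px, 0.0, 1.0)
        uvc[:, c, :, :2] = np.where(visible[..., None], uv + noise, 0.0)
        uvc[:, c, :, 2] = np.where(visible, conf, 0.0)
    return KeypointObservationSet(uvc, list(truth.keypoint_names), truth.frame_rate)


def sample_systematic_offsets(
    keypoints=("RHip", "LHip", "RKnee", "LKnee"),
    magnitude_range: tuple[float, float] = (0.03, 0.05),
    seed: int = 0,
) -> dict:
    """Draw a random systematic-offset table for the named joints.

    The detector bias is subject-independent and bilaterally symmetric, so
    one offset direction is drawn per right-side keypoint and mirrored
    (Z negated) onto the left side; magnitudes are uniform in
    ``magnitude_range`` (meters).
    """
    rng = np.random.default_rng(seed)
    out: dict[str, tuple] = {}
    for kp in keypoints:
        if kp.startswith("L") and ("R" + kp[1:]) in out:
            x, y, z = out["R" + kp[1:]]
            out[kp] = (x, y, -z)
            continue
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        v *= rng.uniform(*magnitude_range)
        out[kp] = tuple(v)
    return out


#: Landmark pairs whose midpoints define joint centers in the reference
#: marker channel.
LANDMARK_PAIRS = {
    "RKnee": ("RKneeMed", "RKneeLat"),
    "LKnee": ("LKneeMed", "LKneeLat"),
    "RAnkle": ("RAnkleMed", "RAnkleLat"),
    "LAnkle": ("LAnkleMed", "LAnkleLat"),
    "RWrist": ("RWristMed", "RWristLat"),
    "LWrist": ("LWristMed", "LWristLat"),
}


def generate_reference_markers(
    truth: GroundTruth, soft_tissue_sd: float = 0.0, seed: int = 0
) -> tuple[list, np.ndarray]:
    """Anatomical-marker trajectories for the reference channel.

    Returns ``(marker_names, positions)`` with independent Gaussian noise of
    ``soft_tissue_sd`` meters per axis; before noise, the midpoint of each
    landmark pair equals the corresponding true joint center exactly.
    """
    for joint, (a, b) in LANDMARK_PAIRS.items():
        if a not in truth.marker_names or b not in truth.marker_names:
            raise GenerationError(f"missing landmark pair {a!r}/{b!r} for {joint!r}")
    rng = np.random.default_rng(seed)
    pos = truth.marker_positions.copy()
    if soft_tissue_sd > 0:
        pos = pos + rng.normal(0.0, soft_tissue_sd, size=pos.shape)
    return list(truth.marker_names), pos
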