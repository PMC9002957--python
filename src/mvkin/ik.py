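"""Measurement-based scaling and constrained inverse kinematics.

Per frame, IK minimizes the weighted sum of squared distances between
experimental 3D keypoints and the model-attached keypoints,

    sum_i w_i * || x_i_exp - x_i_model(q) ||^2  ( + sum_d w_d * q_d^2 )

over the generalized coordinates q, subject to the model's joint locks
(substituted, hence exact), couplings (substituted, hence exact), and limits
(solver bounds).  The zero-angle priors (the second sum, in radians) apply
only to the static scaling solve, where the subject is known to stand
upright with flat feet.  A sequence is solved frame by frame with warm
starts from the previous solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from mvkin.model import DEFAULT_KEYPOINT_WEIGHTS, SkeletalModel
from mvkin.triangulate import Trajectory3D

__all__ = [
    "PoseVector",
    "ScalingError",
    "DegenerateMotionError",
    "scale_model",
    "inverse_kinematics_frame",
    "inverse_kinematics_sequence",
    "IkResult",
    "functional_joint_center",
    "compute_joint_angles",
    "direct_segment_angles",
    "LOWER_LIMB_ANGLES",
    "SAGITTAL_ANGLES",
]

DEG = math.pi / 180.0

#: Right-side lower-limb coordinates reported by default.
LOWER_LIMB_ANGLES = [
    "hip_flexion_r",
    "hip_adduction_r",
    "hip_rotation_r",
    "knee_flexion_r",
    "knee_adduction_r",
    "knee_rotation_r",
    "ankle_flexion_r",
    "subtalar_r",
]

SAGITTAL_ANGLES = ["hip_flexion_r", "knee_flexion_r", "ankle_flexion_r"]


class ScalingError(ValueError):
    """Raised when measurement-based scaling is impossible."""


class DegenerateMotionError(ValueError):
    """Raised by the functional joint-center fit on non-rotating input."""


@dataclass
class PoseVector:
    """One frame's solved generalized coordinates."""

    q: np.ndarray  # free-DOF values, degrees / meters
    frame: int = 0
    rmse: float = np.nan  # unweighted marker RMSE, meters
    converged: bool = True
    valid: bool = True


# --------------------------------------------------------------------- scaling
def _resolve_point(name: str, points: dict) -> np.ndarray:
    """A measurement endpoint: a keypoint name or ``mid(A,B)``."""
    if name.startswith("mid(") and name.endswith(")"):
        a, b = (s.strip() for s in name[4:-1].split(","))
        return 0.5 * (_resolve_point(a, points) + _resolve_point(b, points))
    if name not in points:
        raise ScalingError(f"static frame is missing measurement endpoint {name!r}")
    return np.asarray(points[name], dtype=float)


def scale_model(
    model: SkeletalModel, static_keypoints: dict
) -> tuple[SkeletalModel, dict]:
    """Measurement-based scaling from one static frame.

    Each configured segment group's scale factor is the ratio of the
    experimental inter-keypoint distance to the model distance (averaged
    when several pairs map to one group).  Returns the scaled model and the
    scale set.
    """
    neutral = model.forward_kinematics(model.neutral_pose())
    scales: dict[str, float] = {}
    for m in model.measurements:
        ratios = []
        for a, b in m["pairs"]:
            exp = np.linalg.norm(_resolve_point(a, static_keypoints) - _resolve_point(b, static_keypoints))
            ref = np.linalg.norm(_resolve_point(a, neutral) - _resolve_point(b, neutral))
            if ref <= 0 or exp <= 0:
                raise ScalingError(f"non-positive distance for pair ({a}, {b})")
            ratios.append(exp / ref)
        factor = float(np.mean(ratios))
        for seg in m["segments"]:
            scales[seg] = factor
    return model.with_scales(scales), scales


# ------------------------------------------------------------------------- IK
def _targets_from_dict(model: SkeletalModel, experimental: dict, weights: dict):
    """Match experimental target names to model placements (keypoints first,
    then anatomical markers) and collect weights."""
    names, segs, offsets, w, pos = [], [], [], [], []
    for name, p in experimental.items():
        if p is None:
            continue
        p = np.asarray(p, dtype=float)
        if not np.all(np.isfinite(p)):
            continue
        if name in model.keypoints:
            seg, off = model.keypoints[name]
        elif name in model.markers:
            seg, off = model.markers[name]
        else:
            continue
        names.append(name)
        segs.append(seg)
        offsets.append(np.asarray(off, dtype=float))
        w.append(float(weights.get(name, 1.0)))
        pos.append(p)
    return names, segs, np.array(offsets), np.array(w), np.array(pos)


def inverse_kinematics_frame(
    model: SkeletalModel,
    experimental: dict,
    weights: dict | None = None,
    q_init: np.ndarray | None = None,
    static_priors: dict | None = None,
    max_iterations: int = 200,
    tol: float = 1e-8,
) -> PoseVector:
    """Solve one frame of weighted, constrained inverse kinematics.

    ``experimental`` maps target names to 3D positions (``None``/NaN entries
    are excluded).  Fewer than three valid targets yields an invalid frame.
    Locked and coupled DOFs never enter the optimization, so their returned
    values are exact by construction; limited DOFs are box-bounded.
    """
    weights = weights if weights is not None else DEFAULT_KEYPOINT_WEIGHTS
    names, segs, offsets, w, pos = _targets_from_dict(model, experimental, weights)
    active = w > 0
    if int(np.sum(active)) < 3:
        q0 = model.neutral_pose() if q_init is None else np.asarray(q_init, float)
        return PoseVector(q=q0, rmse=np.nan, converged=False, valid=False)
    segs = [s for s, a in zip(segs, active) if a]
    offsets, w, pos = offsets[active], w[active], pos[active]
    sqrt_w = np.sqrt(w)

    lo, hi = model.bounds_degrees()
    q0 = model.neutral_pose() if q_init is None else np.asarray(q_init, dtype=float)
    q0 = np.clip(q0, lo, hi)

    prior_idx, prior_w = [], []
    if static_priors:
        free = model.free_dof_names
        for dof_name, pw in static_priors.items():
            if dof_name in free and pw > 0:
                prior_idx.append(free.index(dof_name))
                prior_w.append(math.sqrt(pw))
    prior_idx = np.array(prior_idx, dtype=int)
    prior_w = np.array(prior_w)

    scales = model.scales
    scaled_offsets = np.array([scales[s] * o for s, o in zip(segs, offsets)])

    def _model_points(Q: np.ndarray) -> np.ndarray:
        """(B, T, 3) model-attached target positions for a coordinate batch."""
        T = model.segment_transforms_batch(Q)
        out = np.empty((Q.shape[0], len(segs), 3))
        for i, seg in enumerate(segs):
            R, p = T[seg]
            out[:, i] = p + R @ scaled_offsets[i]
        return out

    n_res = 3 * len(segs) + len(prior_idx)

    def residuals_batch(Q: np.ndarray) -> np.ndarray:
        xm = _model_points(Q)
        res = np.empty((Q.shape[0], n_res))
        res[:, : 3 * len(segs)] = (
            sqrt_w[None, :, None] * (xm - pos[None])
        ).reshape(Q.shape[0], -1)
        if len(prior_idx):
            res[:, 3 * len(segs) :] = prior_w[None] * Q[:, prior_idx] * DEG
        return res

    def fun(q: np.ndarray) -> np.ndarray:
        return residuals_batch(q[None])[0]

    fd_step = 1e-6

    def jac(q: np.ndarray) -> np.ndarray:
        # one-sided finite differences evaluated as a single FK batch
        n = len(q)
        Q = np.tile(q, (n + 1, 1))
        Q[np.arange(1, n + 1), np.arange(n)] += fd_step
        res = residuals_batch(Q)
        return (res[1:] - res[0]).T / fd_step

    sol = least_squares(
        fun,
        q0,
        jac=jac,
        bounds=(lo, hi),
        method="trf",
        ftol=tol,
        xtol=tol,
        gtol=tol,
        max_nfev=max_iterations,
    )
    xm = _model_points(sol.x[None])[0]
    rmse = float(np.sqrt(np.mean(np.sum((xm - pos) ** 2, axis=1))))
    return PoseVector(q=sol.x, rmse=rmse, converged=bool(sol.status > 0), valid=True)


@dataclass
class IkResult:
    """Solved pose series with per-frame marker-fit quality."""

    q: np.ndarray  # (frames, n_free) degrees / meters
    coord_names: list
    rmse: np.ndarray  # (frames,) meters
    valid: np.ndarray  # (frames,) bool
    converged: np.ndarray  # (frames,) bool
    frame_rate: float = 30.0

    def angles(self, model: SkeletalModel) -> dict:
        return compute_joint_angles(model, self.q, self.coord_names)


def inverse_kinematics_sequence(
    model: SkeletalModel,
    trajectory: Trajectory3D | dict,
    weights: dict | None = None,
    frame_rate: float | None = None,
    max_iterations: int = 200,
    tol: float = 1e-8,
) -> IkResult:
    """Frame-by-frame IK with warm starts.

    ``trajectory`` is either a :class:`Trajectory3D` or a dict
    ``name -> (frames, 3)`` array.  Frame 0 starts from the neutral pose;
    every subsequent frame starts from the previous solution, which keeps
    the solution branch continuous on band-limited motion.
    """
    if isinstance(trajectory, Trajectory3D):
        names = trajectory.keypoint_names
        F = trajectory.n_frames
        fr = trajectory.frame_rate

        def frame_targets(f):
            return {
                n: (trajectory.positions[f, k] if trajectory.valid[f, k] else None)
                for k, n in enumerate(names)
            }

    else:
        names = list(trajectory)
        F = len(next(iter(trajectory.values())))
        fr = frame_rate or 30.0

        def frame_targets(f):
            return {n: trajectory[n][f] for n in names}

    if F == 0:
        raise ValueError("empty trajectory")
    fr = frame_rate or fr

    nq = len(model.free_dof_names)
    qs = np.zeros((F, nq))
    rmse = np.full(F, np.nan)
    valid = np.zeros(F, dtype=bool)
    converged = np.zeros(F, dtype=bool)
    q_prev = None
    for f in range(F):
        pv = inverse_kinematics_frame(
            model,
            frame_targets(f),
            weights=weights,
            q_init=q_prev,
            max_iterations=max_iterations,
            tol=tol,
        )
        qs[f] = pv.q
        rmse[f] = pv.rmse
        valid[f] = pv.valid
        converged[f] = pv.converged
        if pv.valid:
            q_prev = pv.q
    return IkResult(qs, list(model.free_dof_names), rmse, valid, converged, fr)


# --------------------------------------------------------- functional center
def _sphere_fit(points: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Algebraic least-squares sphere fit (Coope's linearization).

    Returns (center, radius, singular_values) where the singular values of
    the design matrix expose degenerate (e.g. planar) trajectories.
    """
    P = np.asarray(points, dtype=float)
    A = np.hstack([2.0 * P, np.ones((len(P), 1))])
    b = np.sum(P ** 2, axis=1)
    sol, _, _, sv = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + np.dot(center, center)
    radius = math.sqrt(max(r2, 0.0))
    return center, radius, sv


def functional_joint_center(
    marker_trajectories: np.ndarray,
    min_extent: float = 1e-6,
    degeneracy_ratio: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Functional joint center by least-squares sphere fitting.

    ``marker_trajectories`` has shape (markers, frames, 3) and must already
    be expressed in the reference-segment frame (e.g. thigh markers in the
    pelvis frame for the hip).  Each marker trajectory is fit to a sphere;
    the center estimate is the average of the per-marker centers.  Returns
    ``(center, axis_confident)`` where ``axis_confident`` flags coordinate
    directions actually constrained by the motion (planar arcs leave the
    out-of-plane coordinate unconstrained).

    Raises :class:`DegenerateMotionError` for static or purely translated
    markers.
    """
    M = np.asarray(marker_trajectories, dtype=float)
    if M.ndim == 2:
        M = M[None]
    if M.shape[0] < 1 or M.shape[1] < 10:
        raise DegenerateMotionError("need >= 1 marker and >= 10 frames")
    centers = []
    confident = np.ones(3, dtype=bool)
    for traj in M:
        extent = np.linalg.norm(np.ptp(traj, axis=0))
        if extent < min_extent:
            raise DegenerateMotionError("markers do not move: cannot fit a sphere")
        c, _, sv = _sphere_fit(traj)
        centers.append(c)
        # near-zero singular values mean the normal equations do not
        # constrain some direction (planar / small-arc motion)
        rel = sv / sv[0] if len(sv) == 4 and sv[0] > 0 else np.ones(4)
        if len(sv) == 4 and rel[-1] < degeneracy_ratio:
            # identify the weak direction from the null space of the point cloud
            X = traj - traj.mean(axis=0)
            _, s2, Vt = np.linalg.svd(X, full_matrices=False)
            weak = Vt[-1]
            confident &= np.abs(weak) < 0.9
    return np.mean(centers, axis=0), confident


# ----------------------------------------------------------------- angles
def compute_joint_angles(
    model: SkeletalModel,
    q_series: np.ndarray,
    coord_names: list | None = None,
    which: list | None = None,
) -> dict:
    """Extract named coordinate signals (degrees) from a solved pose series.

    Locked and coupled coordinates are resolved through the model so the
    returned table covers every coordinate name requested.  By default the
    right-side lower-limb set is returned.
    """
    q_series = np.atleast_2d(np.asarray(q_series, dtype=float))
    coord_names = coord_names or model.free_dof_names
    if coord_names != model.free_dof_names:
        raise ValueError("q_series must be ordered like the model's free DOFs")
    which = which if which is not None else list(LOWER_LIMB_ANGLES)
    known = {d.name for d in model.dofs}
    for name in which:
        if name not in known:
            raise KeyError(f"unknown coordinate {name!r}")
    F = q_series.shape[0]
    out = {name: np.empty(F) for name in which}
    free = model.free_dof_names
    idx = {n: i for i, n in enumerate(free)}
    for name in which:
        d = model.dof(name)
        if d.kind in ("free", "limited"):
            out[name] = q_series[:, idx[name]].copy()
        elif d.kind == "locked":
            out[name] = np.full(F, d.value)
        else:  # coupled
            master = q_series[:, idx[d.master]]
            out[name] = np.array([d.coupled_value(m) for m in master])
    return out


def _sagittal_angle(v: np.ndarray) -> np.ndarray:
    """Angle (degrees) of a 3D vector from straight-down, in the XY plane."""
    return np.degrees(np.arctan2(v[:, 0], -v[:, 1]))


def direct_segment_angles(positions: np.ndarray, keypoint_names: list) -> dict:
    """Sagittal lower-limb angles computed directly from segment vectors.

    This is the model-free baseline: hip flexion is the angle between the
    trunk axis (mid-hip to neck) and the thigh vector; knee flexion the
    angle between thigh and shank; ankle flexion the shank-foot angle.  All
    are projected on the sagittal (XY) plane.  Systematic keypoint offsets
    propagate into these angles undamped, which is precisely what the
    constrained skeletal model is meant to mitigate.
    """
    idx = {n: i for i, n in enumerate(keypoint_names)}
    P = np.asarray(positions, dtype=float)

    def col(name):
        return P[:, idx[name]]

    midhip = 0.5 * (col("RHip") + col("LHip"))
    trunk = col("Neck") - midhip
    thigh = col("RKnee") - col("RHip")
    shank = col("RAnkle") - col("RKnee")
    foot = col("RBigToe") - col("RHeel")
    trunk_ang = np.degrees(np.arctan2(trunk[:, 0], trunk[:, 1]))
    hip_flex = _sagittal_angle(thigh) + trunk_ang
    knee_flex = _sagittal_angle(shank) - _sagittal_angle(thigh)
    foot_ang = np.degrees(np.arctan2(foot[:, 1], foot[:, 0]))
    ankle_flex = foot_ang - _sagittal_angle(shank)
    return {
        "hip_flexion_r": hip_flex,
        "knee_flexion_r": -knee_flex,
        "ankle_flexion_r": ankle_flex,
    }
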