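"""Confidence-weighted, robust DLT triangulation of 2D keypoints.

Each camera contributes two linear rows to the homogeneous triangulation
system; the rows are multiplied by that camera's keypoint confidence
(weighted DLT).  The robust variant iteratively discards the camera with the
largest reprojection residual until the mean residual drops below a
threshold or only two cameras remain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mvkin.cameras import CameraParams

__all__ = [
    "KeypointObservationSet",
    "Trajectory3D",
    "TriangulationResult",
    "triangulate_point",
    "robust_triangulate",
    "triangulate_sequence",
]


@dataclass
class KeypointObservationSet:
    """Per-frame, per-camera 2D keypoints with confidences.

    ``uvc`` has shape (frames, cameras, keypoints, 3) holding (u, v,
    confidence); missing observations are encoded as confidence 0.
    """

    uvc: np.ndarray
    keypoint_names: list
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        self.uvc = np.asarray(self.uvc, dtype=float)
        if self.uvc.ndim != 4 or self.uvc.shape[-1] != 3:
            raise ValueError("uvc must have shape (frames, cameras, keypoints, 3)")
        conf = self.uvc[..., 2]
        if conf.size and (conf.min() < 0 or conf.max() > 1):
            raise ValueError("confidences must lie in [0, 1]")
        if self.uvc.shape[2] != len(self.keypoint_names):
            raise ValueError("keypoint axis does not match keypoint_names")

    @property
    def n_frames(self) -> int:
        return self.uvc.shape[0]

    @property
    def n_cameras(self) -> int:
        return self.uvc.shape[1]


@dataclass
class Trajectory3D:
    """Triangulated keypoint trajectories with per-sample quality metadata."""

    positions: np.ndarray  # (frames, keypoints, 3) meters; NaN when invalid
    valid: np.ndarray  # (frames, keypoints) bool
    n_cameras_used: np.ndarray  # (frames, keypoints) int
    reproj_error: np.ndarray  # (frames, keypoints) mean pixels, NaN when invalid
    keypoint_names: list
    frame_rate: float = 30.0
    low_quality: np.ndarray | None = None  # (frames, keypoints) bool
    interpolated: np.ndarray | None = None  # gap-filled samples

    def __post_init__(self) -> None:
        if self.low_quality is None:
            self.low_quality = np.zeros(self.valid.shape, dtype=bool)
        if self.interpolated is None:
            self.interpolated = np.zeros(self.valid.shape, dtype=bool)
        if np.any(self.valid & ~self.interpolated & (self.n_cameras_used < 2)):
            raise ValueError("valid samples require at least 2 contributing cameras")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]


@dataclass
class TriangulationResult:
    position: np.ndarray | None  # (3,) or None when invalid
    residuals: np.ndarray  # per-surviving-camera reprojection distance, pixels
    cameras_used: list  # indices into the input observation list
    valid: bool
    low_quality: bool = False

    @property
    def mean_residual(self) -> float:
        return float(np.mean(self.residuals)) if len(self.residuals) else np.nan


def _dlt_solve(obs: list) -> np.ndarray:
    """Solve the confidence-weighted homogeneous DLT system."""
    rows = []
    for u, v, conf, cam in obs:
        P = cam.projection_matrix
        rows.append(conf * (u * P[2] - P[0]))
        rows.append(conf * (v * P[2] - P[1]))
    A = np.vstack(rows)
    _, _, Vt = np.linalg.svd(A)
    X = Vt[-1]
    if abs(X[3]) < 1e-15:
        return np.full(3, np.nan)
    return X[:3] / X[3]


def _reprojection_residuals(point: np.ndarray, obs: list) -> np.ndarray:
    res = np.empty(len(obs))
    Xh = np.append(point, 1.0)
    for i, (u, v, conf, cam) in enumerate(obs):
        x = cam.projection_matrix @ Xh
        if x[2] <= 1e-12:
            res[i] = np.inf
            continue
        res[i] = float(np.hypot(x[0] / x[2] - u, x[1] / x[2] - v))
    return res


def triangulate_point(
    obs: list, min_confidence: float = 0.3
) -> TriangulationResult:
    """Weighted-DLT triangulation from ``(u, v, confidence, CameraParams)``.

    Observations with confidence below ``min_confidence`` are ignored; fewer
    than two usable observations yields an invalid result rather than an
    exception, so per-frame failures can be flagged in a trajectory.
    """
    usable = [(i, o) for i, o in enumerate(obs) if o[2] > min_confidence]
    if len(usable) < 2:
        return TriangulationResult(None, np.array([]), [], valid=False)
    idx, kept = zip(*usable)
    X = _dlt_solve(list(kept))
    if not np.all(np.isfinite(X)):
        return TriangulationResult(None, np.array([]), [], valid=False)
    res = _reprojection_residuals(X, list(kept))
    return TriangulationResult(X, res, list(idx), valid=True)


def robust_triangulate(
    obs: list,
    max_reproj_error: float = 15.0,
    min_confidence: float = 0.3,
) -> TriangulationResult:
    """Weighted DLT with iterative worst-camera exclusion.

    While the mean reprojection residual exceeds ``max_reproj_error`` and
    more than two cameras remain, the camera with the largest residual is
    dropped and the system re-solved.  Ties on the worst residual are broken
    by dropping the lower-confidence observation, then the lower camera
    index, so the procedure is deterministic.  If the threshold is still
    violated with two cameras, the best two-camera solution is returned
    flagged low-quality.
    """
    usable = [(i, o) for i, o in enumerate(obs) if o[2] > min_confidence]
    if len(usable) < 2:
        return TriangulationResult(None, np.array([]), [], valid=False)
    idx = [i for i, _ in usable]
    kept = [o for _, o in usable]
    while True:
        X = _dlt_solve(kept)
        if not np.all(np.isfinite(X)):
            return TriangulationResult(None, np.array([]), [], valid=False)
        res = _reprojection_residuals(X, kept)
        if np.mean(res) <= max_reproj_error or len(kept) <= 2:
            break
        worst = np.max(res)
        tied = [i for i, r in enumerate(res) if r >= worst - 1e-12]
        # drop lower confidence first, then lower camera index
        drop = min(tied, key=lambda i: (kept[i][2], idx[i]))
        del kept[drop], idx[drop]
    low_quality = bool(np.mean(res) > max_reproj_error)
    return TriangulationResult(X, res, idx, valid=True, low_quality=low_quality)


def _fill_gaps(col: np.ndarray, valid: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly interpolate interior invalid runs of length <= max_gap."""
    filled = valid.copy()
    n = len(valid)
    i = 0
    while i < n:
        if not valid[i]:
            j = i
            while j < n and not valid[j]:
                j += 1
            interior = i > 0 and j < n
            if interior and (j - i) <= max_gap:
                for axis in range(3):
                    col[i:j, axis] = np.interp(
                        np.arange(i, j), [i - 1, j], [col[i - 1, axis], col[j, axis]]
                    )
                filled[i:j] = True
            i = j
        else:
            i += 1
    return filled


def triangulate_sequence(
    obs: KeypointObservationSet,
    rig: list[CameraParams],
    max_reproj_error: float = 15.0,
    min_confidence: float = 0.3,
    max_gap: int = 5,
) -> Trajectory3D:
    """Robust triangulation applied independently per frame and keypoint.

    Interior invalid runs up to ``max_gap`` frames are filled by linear
    interpolation; longer gaps (and leading/trailing gaps) stay invalid.
    """
    if len(rig) != obs.n_cameras:
        raise ValueError(
            f"rig has {len(rig)} cameras but observations have {obs.n_cameras}"
        )
    F, C, K, _ = obs.uvc.shape
    positions = np.full((F, K, 3), np.nan)
    valid = np.zeros((F, K), dtype=bool)
    ncams = np.zeros((F, K), dtype=int)
    reproj = np.full((F, K), np.nan)
    lowq = np.zeros((F, K), dtype=bool)
    for f in range(F):
        for k in range(K):
            frame_obs = [
                (obs.uvc[f, c, k, 0], obs.uvc[f, c, k, 1], obs.uvc[f, c, k, 2], rig[c])
                for c in range(C)
            ]
            r = robust_triangulate(frame_obs, max_reproj_error, min_confidence)
            if r.valid:
                positions[f, k] = r.position
                valid[f, k] = True
                ncams[f, k] = len(r.cameras_used)
                reproj[f, k] = r.mean_residual
                lowq[f, k] = r.low_quality
    interp = np.zeros((F, K), dtype=bool)
    for k in range(K):
        filled = _fill_gaps(positions[:, k], valid[:, k], max_gap)
        interp[:, k] = filled & ~valid[:, k]
        valid[:, k] = filled
    return Trajectory3D(
        positions,
        valid,
        ncams,
        reproj,
        list(obs.keypoint_names),
        obs.frame_rate,
        lowq,
        interp,
    )
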