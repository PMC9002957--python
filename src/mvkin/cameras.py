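"""Virtual camera rigs and the pinhole projection model.

World coordinates are right-handed with +Y up and meters as the unit.  A
camera maps a world point ``X`` to camera coordinates ``x_c = R @ X + t``
(``R`` is the world-to-camera rotation) and then to pixels through the
intrinsics ``u = fx * x/z + cx``, ``v = fy * y/z + cy``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CameraParams",
    "ProjectionError",
    "RigConfigurationError",
    "make_rig",
    "project",
    "project_points",
]


class RigConfigurationError(ValueError):
    """Raised for camera rigs that cannot support triangulation."""


class ProjectionError(ValueError):
    """Raised when a projection is geometrically undefined."""


@dataclass(frozen=True)
class CameraParams:
    """One camera's pinhole projection model.

    Parameters
    ----------
    focal_lengths : (fx, fy) in pixels
    principal_point : (cx, cy) in pixels
    rotation : (3, 3) world-to-camera rotation matrix
    translation : (3,) camera translation in meters, ``x_c = R @ X + t``
    image_size : (width, height) in pixels
    """

    focal_lengths: tuple[float, float]
    principal_point: tuple[float, float]
    rotation: np.ndarray
    translation: np.ndarray
    image_size: tuple[int, int] = (1000, 1000)
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3):
            raise ValueError("rotation must be a 3x3 matrix")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if not math.isclose(float(np.linalg.det(R)), 1.0, abs_tol=1e-8):
            raise ValueError("rotation must be proper (det +1)")
        fx, fy = self.focal_lengths
        if fx <= 0 or fy <= 0:
            raise ValueError("focal lengths must be positive")
        cx, cy = self.principal_point
        w, h = self.image_size
        if not (0 <= cx <= w and 0 <= cy <= h):
            raise ValueError("principal point must lie inside the image")

    @property
    def center(self) -> np.ndarray:
        """Camera center in world coordinates."""
        return -self.rotation.T @ self.translation

    @property
    def projection_matrix(self) -> np.ndarray:
        """3x4 projection matrix ``K @ [R | t]``."""
        fx, fy = self.focal_lengths
        cx, cy = self.principal_point
        K = np.array([[fx, 0.0, cx], [0.0, fy, cy], [0.0, 0.0, 1.0]])
        return K @ np.hstack([self.rotation, self.translation[:, None]])


def _look_at(center: np.ndarray, target: np.ndarray, up=(0.0, 1.0, 0.0)) -> np.ndarray:
    """World-to-camera rotation for a camera at ``center`` looking at ``target``."""
    z = np.asarray(target, float) - np.asarray(center, float)
    nz = np.linalg.norm(z)
    if nz == 0:
        raise RigConfigurationError("camera placed on its own target")
    z = z / nz
    up = np.asarray(up, float)
    x = np.cross(up, z)
    nx = np.linalg.norm(x)
    if nx < 1e-12:  # optical axis parallel to up: pick an arbitrary lateral axis
        x = np.cross(np.array([1.0, 0.0, 0.0]), z)
        nx = np.linalg.norm(x)
    x = x / nx
    y = np.cross(z, x)
    return np.vstack([x, y, z])


def make_rig(
    n_cameras: int,
    radius: float,
    heights: float | list[float] = 1.2,
    target=(0.0, 1.0, 0.0),
    focal_length: float = 900.0,
    image_size: tuple[int, int] = (1000, 1000),
) -> list[CameraParams]:
    """Place ``n_cameras`` evenly on a circle, all aimed at ``target``.

    The circle lies in the horizontal (XZ) plane, centered above/below the
    target, at the given height(s).  At least two cameras are required for
    triangulation to be possible.
    """
    if n_cameras < 2:
        raise RigConfigurationError(
            f"need at least 2 cameras for triangulation, got {n_cameras}"
        )
    if radius <= 0:
        raise RigConfigurationError("rig radius must be positive")
    target = np.asarray(target, dtype=float)
    if np.isscalar(heights):
        heights = [float(heights)] * n_cameras
    if len(heights) != n_cameras:
        raise RigConfigurationError("need one height per camera")
    w, h = image_size
    cams = []
    for i in range(n_cameras):
        theta = 2.0 * math.pi * i / n_cameras
        center = np.array(
            [
                target[0] + radius * math.cos(theta),
                heights[i],
                target[2] + radius * math.sin(theta),
            ]
        )
        R = _look_at(center, target)
        t = -R @ center
        cams.append(
            CameraParams(
                focal_lengths=(focal_length, focal_length),
                principal_point=(w / 2.0, h / 2.0),
                rotation=R,
                translation=t,
                image_size=image_size,
                name=f"cam_{i:02d}",
            )
        )
    return cams


def project(point, cam: CameraParams):
    """Project one world point; return ``(u, v)`` or ``None`` when out of view.

    Points behind the image plane are reported out-of-view rather than
    producing a spurious mirrored projection.  Projecting the camera center
    itself is undefined and raises :class:`ProjectionError`.
    """
    p = np.asarray(point, dtype=float).reshape(3)
    xc = cam.rotation @ p + cam.translation
    if np.linalg.norm(xc) < 1e-12:
        raise ProjectionError("point coincides with the camera center")
    if xc[2] <= 1e-9:
        return None
    fx, fy = cam.focal_lengths
    cx, cy = cam.principal_point
    return (fx * xc[0] / xc[2] + cx, fy * xc[1] / xc[2] + cy)


def project_points(points: np.ndarray, cam: CameraParams):
    """Vectorized projection of an (N, 3) array.

    Returns ``(uv, in_front)`` where ``uv`` is (N, 2) (NaN when behind the
    camera) and ``in_front`` is a boolean mask.
    """
    P = np.asarray(points, dtype=float).reshape(-1, 3)
    xc = P @ cam.rotation.T + cam.translation
    z = xc[:, 2]
    in_front = z > 1e-9
    fx, fy = cam.focal_lengths
    cx, cy = cam.principal_point
    uv = np.full((P.shape[0], 2), np.nan)
    zs = np.where(in_front, z, 1.0)
    uv[:, 0] = np.where(in_front, fx * xc[:, 0] / zs + cx, np.nan)
    uv[:, 1] = np.where(in_front, fy * xc[:, 1] / zs + cy, np.nan)
    return uv, in_front


def in_image(uv: np.ndarray, cam: CameraParams) -> np.ndarray:
    """Mask of projections that fall inside the image bounds."""
    w, h = cam.image_size
    u, v = uv[..., 0], uv[..., 1]
    with np.errstate(invalid="ignore"):
        return (u >= 0) & (u <= w) & (v >= 0) & (v <= h)


def rig_to_dict(rig: list[CameraParams]) -> dict:
    """Serializable representation used by the TOML rig files."""
    return {
        cam.name or f"cam_{i:02d}": {
            "focal_lengths": list(map(float, cam.focal_lengths)),
            "principal_point": list(map(float, cam.principal_point)),
            "rotation": [list(map(float, row)) for row in cam.rotation],
            "translation": list(map(float, cam.translation)),
            "image_size": list(map(int, cam.image_size)),
        }
        for i, cam in enumerate(rig)
    }


def rig_from_dict(d: dict) -> list[CameraParams]:
    cams = []
    for name in sorted(d):
        block = d[name]
        cams.append(
            CameraParams(
                focal_lengths=tuple(block["focal_lengths"]),
                principal_point=tuple(block["principal_point"]),
                rotation=np.array(block["rotation"], dtype=float),
                translation=np.array(block["translation"], dtype=float),
                image_size=tuple(block["image_size"]),
                name=name,
            )
        )
    return cams
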