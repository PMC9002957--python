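"""Articulated skeletal model with typed degrees of freedom.

The model is a tree of rigid segments rooted at the pelvis.  Each segment is
attached to its parent at a fixed joint location (expressed in the parent
frame) and rotates about one local axis per rotational degree of freedom.
DOFs are typed:

``free``
    solved by inverse kinematics, optionally box-limited;
``locked``
    held at a constant value (e.g. forearm pronation/supination at 90°,
    wrist flexion and deviation at 0°, because no 2D keypoint informs them);
``limited``
    free but constrained to ``[lo, hi]`` (e.g. hip flexion capped at 150°,
    wide enough for pedaling);
``coupled``
    a deterministic function of a master DOF (knee abduction/adduction and
    internal/external rotation follow knee flexion through a piecewise-linear
    curve; each lumbar vertebra carries an equal share of total lumbar
    flexion).

Angles are degrees at every public interface and radians internally.
Distances are meters.  The world frame is right-handed, +X the progression
direction, +Y up, +Z the subject's right.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Dof",
    "Segment",
    "SkeletalModel",
    "default_model",
    "BODY_KEYPOINTS",
]

DEG = math.pi / 180.0

#: Keypoint naming follows the OpenPose BODY_25B dialect with eye and ear
#: keypoints excluded (21 keypoints).
BODY_KEYPOINTS = [
    "Nose", "Head", "Neck",
    "RShoulder", "RElbow", "RWrist",
    "LShoulder", "LElbow", "LWrist",
    "RHip", "RKnee", "RAnkle", "RBigToe", "RSmallToe", "RHeel",
    "LHip", "LKnee", "LAnkle", "LBigToe", "LSmallToe", "LHeel",
]


@dataclass(frozen=True)
class Segment:
    """Rigid body attached to ``parent`` at ``joint_offset`` (parent frame)."""

    name: str
    parent: str | None
    joint_offset: tuple[float, float, float]


@dataclass(frozen=True)
class Dof:
    """One generalized coordinate.

    ``axis`` is the rotation (or translation) axis in the local joint frame;
    ``segment`` the segment the DOF articulates.  Abstract master coordinates
    (e.g. total lumbar flexion) have ``segment=None`` and move the skeleton
    only through the coupled DOFs that reference them.
    """

    name: str
    kind: str  # "free" | "locked" | "limited" | "coupled"
    segment: str | None = None
    axis: tuple[float, float, float] | None = None
    translation: bool = False
    value: float = 0.0  # locked value, degrees (or meters for translations)
    bounds: tuple[float, float] = (-math.inf, math.inf)  # degrees / meters
    master: str | None = None
    # piecewise-linear coupling: value = interp(master, knots_x, knots_y)
    knots_x: tuple[float, ...] = ()
    knots_y: tuple[float, ...] = ()
    scale: float | None = None  # linear coupling shortcut: value = scale*master

    def coupled_value(self, master_value: float) -> float:
        if self.scale is not None:
            return self.scale * master_value
        return float(np.interp(master_value, self.knots_x, self.knots_y))


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis."""
    x, y, z = axis
    c, s = math.cos(angle), math.sin(angle)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def _axis_rotation_batch(axis: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """(B, 3, 3) Rodrigues rotations about one unit axis."""
    x, y, z = axis
    c = np.cos(angles)
    s = np.sin(angles)
    C = 1.0 - c
    R = np.empty((len(angles), 3, 3))
    R[:, 0, 0] = c + x * x * C
    R[:, 0, 1] = x * y * C - z * s
    R[:, 0, 2] = x * z * C + y * s
    R[:, 1, 0] = y * x * C + z * s
    R[:, 1, 1] = c + y * y * C
    R[:, 1, 2] = y * z * C - x * s
    R[:, 2, 0] = z * x * C - y * s
    R[:, 2, 1] = z * y * C + x * s
    R[:, 2, 2] = c + z * z * C
    return R


class SkeletalModel:
    """Tree of segments, typed DOFs, keypoint placements and scale factors."""

    def __init__(
        self,
        segments: list[Segment],
        dofs: list[Dof],
        keypoints: dict[str, tuple[str, tuple[float, float, float]]],
        measurements: list[dict] | None = None,
        scales: dict[str, float] | None = None,
        markers: dict[str, tuple[str, tuple[float, float, float]]] | None = None,
    ):
        self.segments: dict[str, Segment] = {}
        for seg in segments:
            if seg.parent is not None and seg.parent not in self.segments:
                raise ValueError(
                    f"segment {seg.name!r} listed before its parent {seg.parent!r}"
                )
            self.segments[seg.name] = seg
        roots = [s for s in segments if s.parent is None]
        if len(roots) != 1:
            raise ValueError("segment graph must be a tree with a single root")
        self.root = roots[0].name
        self.dofs = list(dofs)
        self._dof_by_name = {d.name: d for d in dofs}
        for d in dofs:
            if d.kind == "coupled":
                if d.master not in self._dof_by_name:
                    raise ValueError(f"coupled DOF {d.name!r} references unknown master")
            if d.kind == "limited" and not d.bounds[0] < d.bounds[1]:
                raise ValueError(f"DOF {d.name!r} limits must satisfy lo < hi")
            if d.segment is not None and d.segment not in self.segments:
                raise ValueError(f"DOF {d.name!r} references unknown segment")
        self.keypoints = dict(keypoints)
        self.markers = dict(markers or {})
        for name, (seg, _) in {**self.keypoints, **self.markers}.items():
            if seg not in self.segments:
                raise ValueError(f"placement {name!r} references unknown segment {seg!r}")
        self.measurements = list(measurements or [])
        self.scales = {name: 1.0 for name in self.segments}
        if scales:
            for k, v in scales.items():
                if v <= 0:
                    raise ValueError(f"scale factor for {k!r} must be positive")
                self.scales[k] = float(v)
        # DOFs grouped by segment, in declaration order (rotation composition order)
        self._seg_dofs: dict[str, list[Dof]] = {name: [] for name in self.segments}
        for d in dofs:
            if d.segment is not None:
                self._seg_dofs[d.segment].append(d)

    # ------------------------------------------------------------------ DOFs
    @property
    def coordinate_names(self) -> list[str]:
        """All generalized-coordinate names, in declaration order."""
        return [d.name for d in self.dofs]

    @property
    def free_dof_names(self) -> list[str]:
        """Names of the coordinates inverse kinematics solves for."""
        return [d.name for d in self.dofs if d.kind in ("free", "limited")]

    def dof(self, name: str) -> Dof:
        return self._dof_by_name[name]

    def bounds_degrees(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        for d in self.dofs:
            if d.kind in ("free", "limited"):
                lo.append(d.bounds[0])
                hi.append(d.bounds[1])
        return np.array(lo), np.array(hi)

    def resolve_coordinates(self, q: np.ndarray) -> dict[str, float]:
        """Full coordinate dictionary (degrees/meters) from a free-DOF vector.

        Locked DOFs take their locked value; coupled DOFs are evaluated from
        their master.  ``q`` is ordered like :attr:`free_dof_names`.
        """
        q = np.asarray(q, dtype=float)
        free = self.free_dof_names
        if q.shape != (len(free),):
            raise ValueError(
                f"expected {len(free)} generalized coordinates, got {q.shape}"
            )
        values = dict(zip(free, q))
        for d in self.dofs:
            if d.kind == "locked":
                values[d.name] = d.value
        for d in self.dofs:
            if d.kind == "coupled":
                values[d.name] = d.coupled_value(values[d.master])
        return values

    # ------------------------------------------------------- kinematics
    def segment_transforms(
        self, q: np.ndarray
    ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """World pose ``(R, p)`` of every segment for coordinates ``q``."""
        values = self.resolve_coordinates(q)
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for name, seg in self.segments.items():
            if seg.parent is None:
                Rp, pp = np.eye(3), np.zeros(3)
                parent_scale = 1.0
            else:
                Rp, pp = out[seg.parent]
                parent_scale = self.scales[seg.parent]
            p = pp + Rp @ (parent_scale * np.asarray(seg.joint_offset))
            R = Rp
            for d in self._seg_dofs[name]:
                v = values[d.name]
                axis = np.asarray(d.axis, dtype=float)
                if d.translation:
                    p = p + R @ (axis * v)
                else:
                    R = R @ _axis_rotation(axis, v * DEG)
            out[name] = (R, p)
        return out

    def segment_transforms_batch(
        self, Q: np.ndarray
    ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Vectorized :meth:`segment_transforms` for a (B, n_free) batch.

        Returns ``seg -> (R (B, 3, 3), p (B, 3))``.  Used by the IK solver to
        evaluate finite-difference Jacobians in one pass.
        """
        Q = np.atleast_2d(np.asarray(Q, dtype=float))
        B = Q.shape[0]
        free = self.free_dof_names
        if Q.shape[1] != len(free):
            raise ValueError(f"expected {len(free)} coordinates per row")
        values: dict[str, np.ndarray] = {n: Q[:, i] for i, n in enumerate(free)}
        for d in self.dofs:
            if d.kind == "locked":
                values[d.name] = np.full(B, d.value)
        for d in self.dofs:
            if d.kind == "coupled":
                m = values[d.master]
                if d.scale is not None:
                    values[d.name] = d.scale * m
                else:
                    values[d.name] = np.interp(m, d.knots_x, d.knots_y)
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        eye = np.broadcast_to(np.eye(3), (B, 3, 3))
        for name, seg in self.segments.items():
            if seg.parent is None:
                Rp, pp = eye, np.zeros((B, 3))
                parent_scale = 1.0
            else:
                Rp, pp = out[seg.parent]
                parent_scale = self.scales[seg.parent]
            off = parent_scale * np.asarray(seg.joint_offset)
            p = pp + Rp @ off
            R = Rp
            for d in self._seg_dofs[name]:
                v = values[d.name]
                axis = np.asarray(d.axis, dtype=float)
                if d.translation:
                    p = p + (R @ axis) * v[:, None]
                else:
                    R = R @ _axis_rotation_batch(axis, v * DEG)
            out[name] = (R, p)
        return out

    def forward_kinematics(self, q: np.ndarray) -> dict[str, np.ndarray]:
        """World positions of all keypoints for coordinates ``q``."""
        T = self.segment_transforms(q)
        out = {}
        for name, (seg, offset) in self.keypoints.items():
            R, p = T[seg]
            out[name] = p + R @ (self.scales[seg] * np.asarray(offset))
        return out

    def marker_positions(self, q: np.ndarray) -> dict[str, np.ndarray]:
        """World positions of the anatomical reference markers."""
        T = self.segment_transforms(q)
        out = {}
        for name, (seg, offset) in self.markers.items():
            R, p = T[seg]
            out[name] = p + R @ (self.scales[seg] * np.asarray(offset))
        return out

    def keypoint_array(self, q: np.ndarray, names: list[str] | None = None) -> np.ndarray:
        kp = self.forward_kinematics(q)
        names = names or list(self.keypoints)
        return np.array([kp[n] for n in names])

    def neutral_pose(self) -> np.ndarray:
        """Zero pose clipped into the DOF bounds."""
        lo, hi = self.bounds_degrees()
        return np.clip(np.zeros(len(lo)), lo, hi)

    def with_scales(self, scales: dict[str, float]) -> "SkeletalModel":
        merged = dict(self.scales)
        merged.update(scales)
        return SkeletalModel(
            list(self.segments.values()),
            self.dofs,
            self.keypoints,
            self.measurements,
            merged,
            self.markers,
        )

    def with_keypoint_offsets(
        self, offsets: dict[str, tuple[float, float, float]]
    ) -> "SkeletalModel":
        """Shift keypoint placements in their segment frame.

        Mirrors the placement-compensation step in which 2D-detector keypoints
        are positioned on the unscaled model with their known systematic offset
        from the true joint centers.
        """
        kps = dict(self.keypoints)
        for name, off in offsets.items():
            seg, base = kps[name]
            kps[name] = (seg, tuple(np.asarray(base) + np.asarray(off)))
        return SkeletalModel(
            list(self.segments.values()),
            self.dofs,
            kps,
            self.measurements,
            self.scales,
            self.markers,
        )

    # ------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        return {
            "segments": {
                s.name: {"parent": s.parent or "", "joint_offset": list(s.joint_offset)}
                for s in self.segments.values()
            },
            "segment_order": list(self.segments),
            "dofs": [
                {
                    "name": d.name,
                    "kind": d.kind,
                    "segment": d.segment or "",
                    "axis": list(d.axis) if d.axis is not None else [],
                    "translation": d.translation,
                    "value": d.value,
                    "bounds": [d.bounds[0], d.bounds[1]],
                    "master": d.master or "",
                    "knots_x": list(d.knots_x),
                    "knots_y": list(d.knots_y),
                    "scale": d.scale if d.scale is not None else math.nan,
                }
                for d in self.dofs
            ],
            "keypoints": {k: {"segment": s, "offset": list(o)} for k, (s, o) in self.keypoints.items()},
            "markers": {k: {"segment": s, "offset": list(o)} for k, (s, o) in self.markers.items()},
            "measurements": self.measurements,
            "scales": dict(self.scales),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SkeletalModel":
        order = d.get("segment_order", list(d["segments"]))
        segments = [
            Segment(
                name,
                d["segments"][name]["parent"] or None,
                tuple(d["segments"][name]["joint_offset"]),
            )
            for name in order
        ]
        dofs = []
        for dd in d["dofs"]:
            scale = dd.get("scale", math.nan)
            dofs.append(
                Dof(
                    name=dd["name"],
                    kind=dd["kind"],
                    segment=dd["segment"] or None,
                    axis=tuple(dd["axis"]) if dd["axis"] else None,
                    translation=bool(dd.get("translation", False)),
                    value=float(dd.get("value", 0.0)),
                    bounds=tuple(dd.get("bounds", (-math.inf, math.inf))),
                    master=dd.get("master") or None,
                    knots_x=tuple(dd.get("knots_x", ())),
                    knots_y=tuple(dd.get("knots_y", ())),
                    scale=None if (scale is None or math.isnan(scale)) else float(scale),
                )
            )
        keypoints = {
            k: (v["segment"], tuple(v["offset"])) for k, v in d.get("keypoints", {}).items()
        }
        markers = {
            k: (v["segment"], tuple(v["offset"])) for k, v in d.get("markers", {}).items()
        }
        return cls(
            segments,
            dofs,
            keypoints,
            d.get("measurements", []),
            d.get("scales"),
            markers,
        )


def _mirror(offset, side):
    """Mirror a right-side local offset to the left (negate Z)."""
    x, y, z = offset
    return (x, y, z) if side == "r" else (x, y, -z)


def default_model() -> SkeletalModel:
    """Simplified full-body humanoid used throughout the package.

    Pelvis root, a five-vertebra lumbar stack whose flexions are equal shares
    of one master coordinate, torso, head, and left/right thigh-shank-foot and
    upper-arm-forearm-hand chains.  Dimensions approximate a 1.8 m adult.
    The DOF typing encodes the constraint set of the constrained-IK protocol:
    wrist flexion/deviation locked at 0°, forearm pronation/supination locked
    at 90°, pelvis translation and the subtalar angle unlocked, hip flexion
    limited to 150°, and the knee's non-sagittal angles coupled to flexion.
    """
    segments = [
        Segment("pelvis", None, (0.0, 0.0, 0.0)),
        Segment("lumbar5", "pelvis", (0.0, 0.08, 0.0)),
        Segment("lumbar4", "lumbar5", (0.0, 0.04, 0.0)),
        Segment("lumbar3", "lumbar4", (0.0, 0.04, 0.0)),
        Segment("lumbar2", "lumbar3", (0.0, 0.04, 0.0)),
        Segment("lumbar1", "lumbar2", (0.0, 0.04, 0.0)),
        Segment("torso", "lumbar1", (0.0, 0.05, 0.0)),
        Segment("head", "torso", (0.0, 0.30, 0.0)),
    ]
    for side, sz in (("r", 1.0), ("l", -1.0)):
        segments += [
            Segment(f"thigh_{side}", "pelvis", (0.0, -0.07, 0.09 * sz)),
            Segment(f"shank_{side}", f"thigh_{side}", (0.0, -0.42, 0.0)),
            Segment(f"foot_{side}", f"shank_{side}", (0.0, -0.43, 0.0)),
            Segment(f"upperarm_{side}", "torso", (0.0, 0.24, 0.18 * sz)),
            Segment(f"forearm_{side}", f"upperarm_{side}", (0.0, -0.31, 0.0)),
            Segment(f"hand_{side}", f"forearm_{side}", (0.0, -0.27, 0.0)),
        ]

    dofs: list[Dof] = [
        Dof("pelvis_tx", "free", "pelvis", (1, 0, 0), translation=True, bounds=(-50, 50)),
        Dof("pelvis_ty", "free", "pelvis", (0, 1, 0), translation=True, bounds=(-5, 5)),
        Dof("pelvis_tz", "free", "pelvis", (0, 0, 1), translation=True, bounds=(-50, 50)),
        Dof("pelvis_tilt", "limited", "pelvis", (0, 0, 1), bounds=(-90, 90)),
        Dof("pelvis_list", "limited", "pelvis", (1, 0, 0), bounds=(-90, 90)),
        # wide yaw bounds: back-and-forth trials turn through 180 degrees
        Dof("pelvis_rotation", "limited", "pelvis", (0, 1, 0), bounds=(-360, 360)),
        # total lumbar flexion; each vertebra carries one fifth of it
        Dof("lumbar_flexion", "limited", None, bounds=(-30, 60)),
    ]
    for i in (5, 4, 3, 2, 1):
        dofs.append(
            Dof(
                f"lumbar_l{i}_flexion",
                "coupled",
                f"lumbar{i}",
                (0, 0, 1),
                master="lumbar_flexion",
                scale=0.2,
            )
        )
    dofs.append(Dof("neck_flexion", "locked", "head", (0, 0, 1), value=0.0))
    for side in ("r", "l"):
        dofs += [
            Dof(f"arm_flex_{side}", "limited", f"upperarm_{side}", (0, 0, 1), bounds=(-90, 180)),
            Dof(f"arm_add_{side}", "limited", f"upperarm_{side}", (1, 0, 0), bounds=(-150, 150)),
            Dof(f"elbow_flex_{side}", "limited", f"forearm_{side}", (0, 0, 1), bounds=(0, 150)),
            # no keypoint informs these three: locked, exactly as in the protocol
            Dof(f"pro_sup_{side}", "locked", f"forearm_{side}", (0, 1, 0), value=90.0),
            Dof(f"wrist_flex_{side}", "locked", f"hand_{side}", (0, 0, 1), value=0.0),
            Dof(f"wrist_dev_{side}", "locked", f"hand_{side}", (1, 0, 0), value=0.0),
            # hip flexion limit raised to 150 deg so pedaling poses stay feasible
            Dof(f"hip_flexion_{side}", "limited", f"thigh_{side}", (0, 0, 1), bounds=(-30, 150)),
            Dof(f"hip_adduction_{side}", "limited", f"thigh_{side}", (1, 0, 0), bounds=(-50, 50)),
            Dof(f"hip_rotation_{side}", "limited", f"thigh_{side}", (0, 1, 0), bounds=(-40, 40)),
            Dof(f"knee_flexion_{side}", "limited", f"shank_{side}", (0, 0, -1), bounds=(0, 150)),
            Dof(
                f"knee_adduction_{side}",
                "coupled",
                f"shank_{side}",
                (1, 0, 0),
                master=f"knee_flexion_{side}",
                knots_x=(0.0, 90.0, 150.0),
                knots_y=(0.0, 3.0, 4.0),
            ),
            Dof(
                f"knee_rotation_{side}",
                "coupled",
                f"shank_{side}",
                (0, 1, 0),
                master=f"knee_flexion_{side}",
                knots_x=(0.0, 90.0, 150.0),
                knots_y=(0.0, 8.0, 12.0),
            ),
            Dof(f"ankle_flexion_{side}", "limited", f"foot_{side}", (0, 0, 1), bounds=(-50, 50)),
            # subtalar inversion/eversion unlocked
            Dof(f"subtalar_{side}", "limited", f"foot_{side}", (1, 0, 0), bounds=(-35, 35)),
        ]

    keypoints = {
        "Nose": ("head", (0.10, 0.10, 0.0)),
        "Head": ("head", (0.0, 0.15, 0.0)),
        "Neck": ("torso", (0.0, 0.28, 0.0)),
    }
    for side, S in (("r", "R"), ("l", "L")):
        keypoints |= {
            f"{S}Shoulder": (f"upperarm_{side}", (0.0, 0.0, 0.0)),
            f"{S}Elbow": (f"forearm_{side}", (0.0, 0.0, 0.0)),
            f"{S}Wrist": (f"hand_{side}", (0.0, 0.0, 0.0)),
            f"{S}Hip": (f"thigh_{side}", (0.0, 0.0, 0.0)),
            f"{S}Knee": (f"shank_{side}", (0.0, 0.0, 0.0)),
            f"{S}Ankle": (f"foot_{side}", (0.0, 0.0, 0.0)),
            f"{S}BigToe": (f"foot_{side}", _mirror((0.16, -0.03, -0.02), side)),
            f"{S}SmallToe": (f"foot_{side}", _mirror((0.14, -0.03, 0.035), side)),
            f"{S}Heel": (f"foot_{side}", (-0.06, -0.03, 0.0)),
        }

    # Anatomical reference markers for the marker-based channel: bony-landmark
    # pairs whose midpoints are the joint centers, a sacrum marker, and thigh
    # cluster markers used by the functional hip-center method.
    markers: dict[str, tuple[str, tuple[float, float, float]]] = {
        "Sacrum": ("pelvis", (-0.12, 0.02, 0.0)),
    }
    for side, S in (("r", "R"), ("l", "L")):
        markers |= {
            f"{S}KneeMed": (f"thigh_{side}", _mirror((0.0, -0.42, -0.05), side)),
            f"{S}KneeLat": (f"thigh_{side}", _mirror((0.0, -0.42, 0.05), side)),
            f"{S}AnkleMed": (f"shank_{side}", _mirror((0.0, -0.43, -0.04), side)),
            f"{S}AnkleLat": (f"shank_{side}", _mirror((0.0, -0.43, 0.04), side)),
            f"{S}WristMed": (f"forearm_{side}", _mirror((0.0, -0.27, -0.03), side)),
            f"{S}WristLat": (f"forearm_{side}", _mirror((0.0, -0.27, 0.03), side)),
            f"{S}Heel": (f"foot_{side}", (-0.06, -0.03, 0.0)),
            f"{S}Toe": (f"foot_{side}", (0.16, -0.03, 0.0)),
            f"{S}Thigh1": (f"thigh_{side}", _mirror((0.06, -0.20, 0.03), side)),
            f"{S}Thigh2": (f"thigh_{side}", _mirror((0.02, -0.28, 0.06), side)),
            f"{S}Thigh3": (f"thigh_{side}", _mirror((-0.03, -0.22, 0.04), side)),
            f"{S}Thigh4": (f"thigh_{side}", _mirror((0.04, -0.14, 0.05), side)),
        }

    # The pelvis is scaled with the trunk's vertical measurement rather than
    # the hip-to-hip width: hip keypoint spacing is exactly the quantity the
    # 2D detectors mislocalize, and an inflated pelvis height feeds a
    # lordotic/kyphotic spine ambiguity into every hip angle.
    trunk = ["lumbar5", "lumbar4", "lumbar3", "lumbar2", "lumbar1", "torso"]
    measurements = [
        {"segments": ["pelvis"] + trunk, "pairs": [["mid(RHip,LHip)", "Neck"]]},
        {"segments": ["head"], "pairs": [["Neck", "Head"]]},
        {"segments": ["thigh_r"], "pairs": [["RHip", "RKnee"]]},
        {"segments": ["thigh_l"], "pairs": [["LHip", "LKnee"]]},
        {"segments": ["shank_r"], "pairs": [["RKnee", "RAnkle"]]},
        {"segments": ["shank_l"], "pairs": [["LKnee", "LAnkle"]]},
        {"segments": ["foot_r"], "pairs": [["RHeel", "RBigToe"]]},
        {"segments": ["foot_l"], "pairs": [["LHeel", "LBigToe"]]},
        {"segments": ["upperarm_r"], "pairs": [["RShoulder", "RElbow"]]},
        {"segments": ["upperarm_l"], "pairs": [["LShoulder", "LElbow"]]},
        {"segments": ["forearm_r", "hand_r"], "pairs": [["RElbow", "RWrist"]]},
        {"segments": ["forearm_l", "hand_l"], "pairs": [["LElbow", "LWrist"]]},
    ]
    return SkeletalModel(segments, dofs, keypoints, measurements, None, markers)


#: Keypoint weights of the IK/scaling objective: 1 everywhere except the face
#: keypoints (0.1) and the shoulder/hip keypoints (2).
DEFAULT_KEYPOINT_WEIGHTS: dict[str, float] = {
    **{name: 1.0 for name in BODY_KEYPOINTS},
    "Nose": 0.1,
    "Head": 0.1,
    "RShoulder": 2.0,
    "LShoulder": 2.0,
    "RHip": 2.0,
    "LHip": 2.0,
}

#: Zero-angle prior weights used only in the static (scaling) solve: the
#: static trial is an upright stance with flat feet.
DEFAULT_STATIC_PRIORS: dict[str, float] = {
    "pelvis_list": 1.0,
    "pelvis_tilt": 1.0,
    "lumbar_flexion": 1.0,
    "ankle_flexion_r": 1.0,
    "ankle_flexion_l": 1.0,
    "subtalar_r": 1.0,
    "subtalar_l": 1.0,
}
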