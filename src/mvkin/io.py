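"""Readers and writers for the pipeline's interchange formats.

* OpenPose-dialect JSON: one file per frame per camera,
  ``{"people": [{"pose_keypoints_2d": [x1, y1, c1, ...]}]}``;
* TRC marker trajectories and MOT joint-coordinate files (tab-separated,
  OpenSim-ecosystem conventions, 6-decimal float formatting);
* a minimal TOML emitter for rig / model / config files (read via tomllib).
"""

from __future__ import annotations

import json
import math
import tomllib
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from mvkin.triangulate import KeypointObservationSet, Trajectory3D

__all__ = [
    "write_openpose_json",
    "read_openpose_json",
    "write_trc",
    "read_trc",
    "write_mot",
    "read_mot",
    "toml_dumps",
    "load_toml",
    "save_toml",
]


class ParseError(ValueError):
    pass


# ----------------------------------------------------------------- OpenPose
def write_openpose_json(obs: KeypointObservationSet, out_dir) -> None:
    """One subdirectory per camera, one JSON file per frame."""
    out_dir = Path(out_dir)
    F, C, K, _ = obs.uvc.shape
    for c in range(C):
        cam_dir = out_dir / f"cam_{c:02d}"
        cam_dir.mkdir(parents=True, exist_ok=True)
        for f in range(F):
            triplets = obs.uvc[f, c].reshape(-1).tolist()
            payload = {
                "version": 1.3,
                "people": [{"pose_keypoints_2d": triplets}],
            }
            (cam_dir / f"frame_{f:06d}.json").write_text(json.dumps(payload))
    meta = {"keypoint_names": list(obs.keypoint_names), "frame_rate": obs.frame_rate}
    (out_dir / "keypoints.json").write_text(json.dumps(meta, indent=1))


def read_openpose_json(
    in_dir,
    keypoint_names: list | None = None,
    frame_rate: float | None = None,
    strict: bool = True,
) -> KeypointObservationSet:
    """Parse a per-camera directory tree of per-frame OpenPose JSON files.

    Missing trailing frames are padded with confidence 0; a frame-count
    mismatch across cameras is reported with the counts.  Files with several
    detected people either error (strict) or take the first person.
    """
    in_dir = Path(in_dir)
    meta_path = in_dir / "keypoints.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        keypoint_names = keypoint_names or meta.get("keypoint_names")
        frame_rate = frame_rate or meta.get("frame_rate")
    cam_dirs = sorted(d for d in in_dir.iterdir() if d.is_dir())
    if not cam_dirs:
        raise ParseError(f"no per-camera subdirectories found in {in_dir}")
    per_cam = []
    counts = {}
    for cam_dir in cam_dirs:
        files = sorted(cam_dir.glob("*.json"))
        counts[cam_dir.name] = len(files)
        frames = []
        for fp in files:
            try:
                payload = json.loads(fp.read_text())
            except json.JSONDecodeError as e:
                raise ParseError(f"malformed JSON in {fp}: {e}") from e
            people = payload.get("people", [])
            if len(people) == 0:
                frames.append(None)
                continue
            if len(people) > 1 and strict:
                raise ParseError(f"{fp} contains {len(people)} people (strict mode)")
            frames.append(np.asarray(people[0]["pose_keypoints_2d"], float).reshape(-1, 3))
        per_cam.append(frames)
    n_frames = max(counts.values())
    if len(set(counts.values())) > 1:
        raise ParseError(f"frame-count mismatch across cameras: {counts}")
    k_sizes = {f.shape[0] for frames in per_cam for f in frames if f is not None}
    if not k_sizes:
        raise ParseError(f"no keypoint data found under {in_dir}")
    K = k_sizes.pop()
    if k_sizes:
        raise ParseError("inconsistent keypoint counts across files")
    if keypoint_names is not None and len(keypoint_names) != K:
        raise ParseError(
            f"expected {len(keypoint_names)} keypoints, files carry {K}"
        )
    uvc = np.zeros((n_frames, len(per_cam), K, 3))
    for c, frames in enumerate(per_cam):
        for f, data in enumerate(frames):
            if data is not None:
                uvc[f, c] = data
    names = keypoint_names if keypoint_names is not None else [f"kp_{i}" for i in range(K)]
    return KeypointObservationSet(uvc, list(names), frame_rate or 30.0)


# ---------------------------------------------------------------------- TRC
def write_trc(path, names: list, positions: np.ndarray, frame_rate: float) -> None:
    """Tab-separated TRC with DataRate/NumFrames/Units header, units meters."""
    P = np.asarray(positions, dtype=float)
    F, M, _ = P.shape
    path = Path(path)
    lines = [
        f"PathFileType\t4\t(X/Y/Z)\t{path.name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\tOrigDataStartFrame\tOrigNumFrames",
        f"{frame_rate:g}\t{frame_rate:g}\t{F}\t{M}\tm\t{frame_rate:g}\t1\t{F}",
        "Frame#\tTime\t" + "\t\t\t".join(names) + "\t\t",
        "\t\t" + "\t".join(f"X{i}\tY{i}\tZ{i}" for i in range(1, M + 1)),
        "",
    ]
    for f in range(F):
        vals = "\t".join(f"{v:.6f}" for v in P[f].reshape(-1))
        lines.append(f"{f + 1}\t{f / frame_rate:.6f}\t{vals}")
    path.write_text("\n".join(lines) + "\n")


def read_trc(path) -> tuple[list, np.ndarray, float]:
    """Returns ``(marker_names, positions (F, M, 3) in meters, frame_rate)``.

    Millimeter files are converted to meters with a warning.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 6:
        raise ParseError(f"{path}: truncated TRC file ({len(lines)} lines)")
    header_keys = lines[1].split("\t")
    header_vals = lines[2].split("\t")
    header = dict(zip(header_keys, header_vals))
    try:
        frame_rate = float(header["DataRate"])
        n_markers = int(header["NumMarkers"])
        units = header.get("Units", "m")
    except (KeyError, ValueError) as e:
        raise ParseError(f"{path}: malformed TRC header: {e}") from e
    names = [n for n in lines[3].split("\t")[2:] if n]
    if len(names) != n_markers:
        raise ParseError(
            f"{path}: header says {n_markers} markers, label row has {len(names)}"
        )
    rows = []
    for i, line in enumerate(lines[5:], start=6):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2 + 3 * n_markers:
            raise ParseError(f"{path}: truncated data row at line {i}")
        rows.append([float(v) if v else math.nan for v in parts[2 : 2 + 3 * n_markers]])
    P = np.asarray(rows).reshape(len(rows), n_markers, 3)
    if units.lower() == "mm":
        warnings.warn(f"{path}: converting mm to m", stacklevel=2)
        P = P / 1000.0
    return names, P, frame_rate


# ---------------------------------------------------------------------- MOT
def write_mot(path, columns: dict, frame_rate: float, in_degrees: bool = True) -> None:
    """OpenSim-style MOT: name, nRows/nColumns, inDegrees, endheader, data."""
    path = Path(path)
    names = list(columns)
    F = len(next(iter(columns.values())))
    lines = [
        path.stem,
        "version=1",
        f"nRows={F}",
        f"nColumns={len(names) + 1}",
        f"inDegrees={'yes' if in_degrees else 'no'}",
        "endheader",
        "time\t" + "\t".join(names),
    ]
    for f in range(F):
        vals = "\t".join(f"{columns[n][f]:.6f}" for n in names)
        lines.append(f"{f / frame_rate:.6f}\t{vals}")
    path.write_text("\n".join(lines) + "\n")


def read_mot(path) -> tuple[dict, float]:
    """Returns ``(columns dict incl. 'time', frame_rate)``, values in degrees."""
    path = Path(path)
    lines = path.read_text().splitlines()
    in_degrees = True
    i = 0
    found_end = False
    for i, line in enumerate(lines):
        low = line.strip().lower()
        if low.startswith("indegrees"):
            in_degrees = low.split("=")[1].strip() == "yes"
        if low == "endheader":
            found_end = True
            break
    if not found_end:
        raise ParseError(f"{path}: missing endheader")
    header = lines[i + 1].split("\t")
    data = []
    for j, line in enumerate(lines[i + 2 :], start=i + 3):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(header):
            raise ParseError(f"{path}: malformed data row at line {j}")
        data.append([float(v) for v in parts])
    arr = np.asarray(data)
    cols = {name: arr[:, k].copy() for k, name in enumerate(header)}
    if not in_degrees:
        for name in header[1:]:
            cols[name] = np.degrees(cols[name])
    t = cols["time"]
    frame_rate = 1.0 / float(np.mean(np.diff(t))) if len(t) > 1 else 0.0
    return cols, frame_rate


# --------------------------------------------------------------------- TOML
def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        if math.isnan(v):
            return "nan"
        if math.isinf(v):
            return "inf" if v > 0 else "-inf"
        return repr(float(v))
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple, np.ndarray)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def _is_table(v) -> bool:
    return isinstance(v, dict)


def toml_dumps(data: dict, prefix: str = "") -> str:
    """Serialize nested dicts of scalars/lists to TOML text."""
    scalars, tables, table_arrays = [], [], []
    for key, v in data.items():
        if _is_table(v):
            tables.append((key, v))
        elif isinstance(v, list) and v and all(_is_table(x) for x in v):
            table_arrays.append((key, v))
        else:
            scalars.append((key, v))
    out = []
    for key, v in scalars:
        out.append(f"{key} = {_toml_value(v)}")
    for key, v in tables:
        name = f"{prefix}{key}"
        out.append(f"\n[{json.dumps(name) if ('.' in key or ' ' in key) else name}]")
        out.append(toml_dumps(v, prefix=name + "."))
    for key, arr in table_arrays:
        name = f"{prefix}{key}"
        for item in arr:
            out.append(f"\n[[{name}]]")
            out.append(toml_dumps(item, prefix=name + "."))
    return "\n".join(s for s in out if s)


def save_toml(path, data: dict) -> None:
    Path(path).write_text(toml_dumps(data) + "\n")


def load_toml(path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


# ------------------------------------------------------------------ helpers
def write_trajectory_quality(path, traj: Trajectory3D) -> None:
    """Per-frame quality CSV: cameras used and mean reprojection residual."""
    F, K = traj.valid.shape
    rows = []
    for f in range(F):
        for k in range(K):
            rows.append(
                {
                    "frame": f,
                    "keypoint": traj.keypoint_names[k],
                    "valid": bool(traj.valid[f, k]),
                    "n_cameras_used": int(traj.n_cameras_used[f, k]),
                    "mean_reproj_px": float(traj.reproj_error[f, k]),
                    "interpolated": bool(traj.interpolated[f, k]),
                    "low_quality": bool(traj.low_quality[f, k]),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_cycles_csv(path, cycles) -> None:
    rows = [
        {
            "cycle": i,
            "start": s,
            "end": e,
            "direction": float(cycles.direction_per_cycle[i]),
        }
        for i, (s, e) in enumerate(cycles.cycles)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cycles_csv(path, normalized_length: int = 101):
    from mvkin.timeseries import CycleSet

    df = pd.read_csv(path)
    cycles = [(int(r.start), int(r.end)) for r in df.itertuples()]
    events = sorted({s for s, _ in cycles} | {e for _, e in cycles})
    return CycleSet(
        np.asarray(events, dtype=int),
        cycles,
        normalized_length,
        df["direction"].to_numpy(),
    )
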