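"""Readers and writers for the pipeline's on-disk formats.

Frame clouds travel as PLY (binary little-endian, via trimesh) or plain XYZ
tables; poses as JSON row-major 4x4 matrices (mm); everything tabular as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .exceptions import InvalidArgumentError
from .se3 import RigidTransform
from .synthetic import FrameSeries


def write_frame_series(series: FrameSeries, out_dir: str | Path, fmt: str = "ply") -> list[Path]:
    """Write one subject's frames as frame_000.ply / .stl / .xyz files.

    STL requires a surface, so clouds are exported via their convex hull in
    that format; PLY and XYZ keep the raw points.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, pts in enumerate(series.frames):
        path = out_dir / f"frame_{k:03d}.{fmt}"
        if fmt == "ply":
            trimesh.PointCloud(pts).export(path)
        elif fmt == "stl":
            trimesh.PointCloud(pts).convex_hull.export(path)
        elif fmt == "xyz":
            np.savetxt(path, pts, fmt="%.6f")
        else:
            raise InvalidArgumentError(f"unsupported frame format: {fmt!r}")
        paths.append(path)
    return paths


def read_frame_series(
    frames_dir: str | Path, subject_id: str, laterality: str
) -> FrameSeries:
    """Load a frame directory (sorted by filename) back into a FrameSeries."""
    frames_dir = Path(frames_dir)
    paths = sorted(
        p for p in frames_dir.iterdir() if p.suffix.lower() in (".ply", ".stl", ".xyz", ".csv")
    )
    if not paths:
        raise InvalidArgumentError(f"no frame files found in {frames_dir}")
    frames = []
    for p in paths:
        if p.suffix.lower() in (".xyz", ".csv"):
            delim = "," if p.suffix.lower() == ".csv" else None
            frames.append(np.loadtxt(p, delimiter=delim, ndmin=2))
        else:
            geom = trimesh.load(p)
            frames.append(np.asarray(geom.vertices, dtype=float))
    return FrameSeries(subject_id=subject_id, frames=frames, laterality=laterality)


def write_poses_json(poses: list[RigidTransform], path: str | Path) -> None:
    payload = [pose.matrix().reshape(-1).tolist() for pose in poses]
    Path(path).write_text(json.dumps({"unit": "mm", "layout": "row-major-4x4", "poses": payload}))


def read_poses_json(path: str | Path) -> list[RigidTransform]:
    payload = json.loads(Path(path).read_text())
    poses = []
    for flat in payload["poses"]:
        M = np.asarray(flat, dtype=float).reshape(4, 4)
        poses.append(RigidTransform(M[:3, :3], M[:3, 3]))
    return poses


def write_poses_csv(poses: list[RigidTransform], path: str | Path) -> None:
    """Poses as CSV: frame index + 12 row-major rotation/translation entries."""
    rows = [pose.matrix()[:3, :].reshape(-1) for pose in poses]
    df = pd.DataFrame(rows, columns=[f"m{i}{j}" for i in range(3) for j in range(4)])
    df.index.name = "frame"
    df.to_csv(path)


def write_dof_csv(samples: np.ndarray, path: str | Path) -> None:
    df = pd.DataFrame(samples, columns=["Tx", "Ty", "Tz", "Rx", "Ry", "Rz"])
    df.index.name = "frame"
    df.to_csv(path)


def read_dof_csv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, index_col="frame").to_numpy(dtype=float)


def read_landmarks(path: str | Path) -> dict[str, np.ndarray]:
    """Named landmark points (mm) from JSON ({name: [x,y,z]}) or CSV."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
        return {k: np.asarray(v, dtype=float) for k, v in raw.items()}
    df = pd.read_csv(path)
    return {
        row["name"]: np.array([row["x"], row["y"], row["z"]], dtype=float)
        for _, row in df.iterrows()
    }
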