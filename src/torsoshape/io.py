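"""Point-cloud file formats, plain-text configuration and run logging.

Coordinate convention throughout the package: millimetres, z vertical
(global up), participant facing -x.  Readers return plain (N, 3) float
arrays and ignore faces, normals and colours.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np


def read_point_cloud(path) -> np.ndarray:
    """Read a PLY (ascii / binary little-endian), OBJ (v records) or
    whitespace XYZ file into an (N, 3) array of mm coordinates."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ext = path.suffix.lower()
    if ext in (".xyz", ".txt"):
        return _read_xyz(path)
    if ext == ".obj":
        return _read_obj(path)
    if ext == ".ply":
        return _read_ply(path)
    raise ValueError(f"unknown point-cloud extension {ext!r}")


def _read_xyz(path: Path) -> np.ndarray:
    pts = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 coordinates, "
                                 f"got {len(fields)}")
            try:
                pts.append([float(v) for v in fields[:3]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if not pts:
        raise ValueError(f"{path}: empty point cloud")
    return np.asarray(pts, dtype=float)


def _read_obj(path: Path) -> np.ndarray:
    pts = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("v "):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: malformed vertex record")
            try:
                pts.append([float(v) for v in fields[1:4]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if not pts:
        raise ValueError(f"{path}: no vertex records")
    return np.asarray(pts, dtype=float)


def _read_ply(path: Path) -> np.ndarray:
    import trimesh

    loaded = trimesh.load(str(path), process=False)
    verts = np.asarray(loaded.vertices, dtype=float)
    if verts.size == 0:
        raise ValueError(f"{path}: empty point cloud")
    return verts


def write_xyz(path, points: np.ndarray) -> None:
    points = np.asarray(points, dtype=float)
    with open(path, "w") as fh:
        for p in points:
            # repr round-trips doubles exactly, keeping re-reads lossless
            fh.write(f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n")


def write_ply(path, points: np.ndarray, binary: bool = False) -> None:
    """Write a vertex-only PLY; ascii output is byte-deterministic."""
    points = np.asarray(points, dtype=float)
    fmt = "binary_little_endian" if binary else "ascii"
    header = ("ply\n"
              f"format {fmt} 1.0\n"
              f"element vertex {len(points)}\n"
              "property double x\nproperty double y\nproperty double z\n"
              "end_header\n")
    if binary:
        with open(path, "wb") as fh:
            fh.write(header.encode("ascii"))
            fh.write(points.astype("<f8").tobytes())
    else:
        with open(path, "w") as fh:
            fh.write(header)
            for p in points:
                fh.write(f"{float(p[0])!r} {float(p[1])!r} "
                         f"{float(p[2])!r}\n")


def write_config(path, obj) -> None:
    """Serialise a (possibly nested) dataclass as key = value text."""
    with open(path, "w") as fh:
        for key, val in dataclasses.asdict(obj).items():
            fh.write(f"{key} = {val!r}\n")


def read_config_dict(path) -> dict:
    """Parse a key = value config file; values via ast.literal_eval."""
    import ast

    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, raw = line.partition("=")
            try:
                out[key.strip()] = ast.literal_eval(raw.strip())
            except (ValueError, SyntaxError) as exc:
                raise ValueError(f"{path}:{lineno}: bad value: {exc}") from exc
    return out
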