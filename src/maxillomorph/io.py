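"""Serialization of meshes, landmarks, region labels, rims and transforms."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict

import numpy as np
import trimesh

from .geometry import RigidTransform
from .planner import LandmarkSet


def load_mesh(path) -> trimesh.Trimesh:
    mesh = trimesh.load(str(path), force="mesh", process=False)
    return trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)


def save_mesh(mesh: trimesh.Trimesh, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mesh.export(str(path))
    return path


def save_landmarks(landmarks: LandmarkSet, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(landmarks.to_dict(), indent=1, sort_keys=True))
    return path


def load_landmarks(path) -> LandmarkSet:
    return LandmarkSet.from_dict(json.loads(Path(path).read_text()))


def save_regions(region_faces: Dict[str, np.ndarray], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {k: np.asarray(v, dtype=int).tolist() for k, v in region_faces.items()}
    path.write_text(json.dumps(payload, sort_keys=True))
    return path


def load_regions(path) -> Dict[str, np.ndarray]:
    raw = json.loads(Path(path).read_text())
    return {k: np.asarray(v, dtype=int) for k, v in raw.items()}


def save_rims(rims: Dict[str, np.ndarray], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps({k: np.asarray(v).tolist() for k, v in rims.items()}, sort_keys=True))
    return path


def load_rims(path) -> Dict[str, np.ndarray]:
    raw = json.loads(Path(path).read_text())
    return {k: np.asarray(v, dtype=float) for k, v in raw.items()}


def save_transform(T: RigidTransform, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(T.to_dict()))
    return path


def load_transform(path) -> RigidTransform:
    return RigidTransform.from_dict(json.loads(Path(path).read_text()))
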