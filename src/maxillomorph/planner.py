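"""Reconstruction landmarks and the two-segment cutting-guide template.

A two-segment free-fibula reconstruction of a hemimaxillectomy defect is
planned from seven named points per hemi-maxilla: the midline A-point, the
deepest point of the inferior orbital rim (IOr/IOl), the caudal-lateral
zygoma point J, its foot point O on the orbital rim, the midpoint M of JO,
and the premolar apex X.  The anterior segment runs from A to X (length AX),
the posterior segment from X to M (length MX), and the bend between the two
fibula segments is the 3-point angle at their shared endpoint X.  Per-side
measurements over a cohort are pooled into a mean-value template.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import RigidTransform

SIDES = ("left", "right")

__all__ = [
    "LandmarkSet",
    "SegmentMeasurement",
    "CuttingGuideTemplate",
    "locate_J",
    "locate_O",
    "construct_landmarks",
    "three_point_angle",
    "measure_segments",
    "pool_sides",
]


class PlannerError(ValueError):
    pass


@dataclass
class LandmarkSet:
    """Named anatomical points (mm).  Keys: ``A``, ``IOr``, ``IOl`` and
    per-side ``J_left`` ... ``X_right``."""

    points: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = {k: np.asarray(v, dtype=float).reshape(3) for k, v in self.points.items()}
        for k, v in self.points.items():
            if not np.all(np.isfinite(v)):
                raise PlannerError(f"landmark {k!r} is not finite")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def names(self):
        return self.points.keys()

    def transform(self, T: RigidTransform) -> "LandmarkSet":
        return LandmarkSet({k: T.apply(v) for k, v in self.points.items()})

    def alignment_triplet(self) -> np.ndarray:
        """(A, IOr, IOl) stacked — the 3-point alignment landmarks."""
        try:
            return np.stack([self.points["A"], self.points["IOr"], self.points["IOl"]])
        except KeyError as e:
            raise PlannerError(f"missing alignment landmark {e.args[0]!r}") from e

    def to_dict(self) -> dict:
        return {k: v.tolist() for k, v in self.points.items()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "LandmarkSet":
        return cls({k: np.asarray(v, dtype=float) for k, v in d.items()})


@dataclass
class SegmentMeasurement:
    """Segment lengths AX and MX (mm) and the bend angle at X (degrees)."""

    side: str
    length_AX: float
    length_MX: float
    angle_deg: float
    subject_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise PlannerError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.length_AX <= 0 or self.length_MX <= 0:
            raise PlannerError("segment lengths must be positive")
        if not (0.0 < self.angle_deg <= 180.0):
            raise PlannerError("angle must lie in (0, 180] degrees")


def locate_J(mesh, zygoma_faces, weights: Sequence[float] = (1.0, 1.0)) -> np.ndarray:
    """Most caudal-lateral vertex of the zygomatic region.

    Scores every region vertex with ``w_c * caudal + w_l * lateral`` where
    caudal (-z) and lateral (|x|) are standardized to the region's bounding
    box; ties go to the lowest vertex index.
    """
    zygoma_faces = np.asarray(zygoma_faces, dtype=int)
    if zygoma_faces.size == 0:
        raise PlannerError("zygoma region is empty")
    vids = np.unique(mesh.faces[zygoma_faces])  # sorted ascending
    v = mesh.vertices[vids]
    z = v[:, 2]
    lat = np.abs(v[:, 0])

    def standardize(u):
        rng = u.max() - u.min()
        return (u - u.min()) / rng if rng > 0 else np.zeros_like(u)

    score = weights[0] * standardize(-z) + weights[1] * standardize(lat)
    return v[int(np.argmax(score))].copy()


def locate_O(rim_polyline: np.ndarray, J: np.ndarray) -> np.ndarray:
    """Closest point on the orbital-rim polyline (segment interiors included) to J.

    Equidistant segments resolve to the earlier one along the polyline.
    """
    rim = np.asarray(rim_polyline, dtype=float).reshape(-1, 3)
    if len(rim) < 2:
        raise PlannerError("rim polyline needs at least 2 vertices")
    J = np.asarray(J, dtype=float).reshape(3)
    p, q = rim[:-1], rim[1:]
    d = q - p
    denom = np.einsum("ij,ij->i", d, d)
    t = np.where(denom > 0, np.einsum("ij,ij->i", J - p, d) / np.where(denom > 0, denom, 1.0), 0.0)
    t = np.clip(t, 0.0, 1.0)
    cand = p + t[:, None] * d
    dist = np.linalg.norm(cand - J, axis=1)
    return cand[int(np.argmin(dist))].copy()  # argmin keeps the earliest on ties


def three_point_angle(P: np.ndarray, V: np.ndarray, Q: np.ndarray) -> float:
    """Angle at vertex V between legs VP and VQ, in degrees, range (0, 180]."""
    u = np.asarray(P, dtype=float) - np.asarray(V, dtype=float)
    w = np.asarray(Q, dtype=float) - np.asarray(V, dtype=float)
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    if nu == 0.0 or nw == 0.0:
        raise PlannerError("zero-length leg in 3-point angle")
    c = np.clip(np.dot(u, w) / (nu * nw), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def construct_landmarks(
    mesh,
    region_labels: Mapping[str, np.ndarray],
    rim_polylines: Mapping[str, np.ndarray],
    annotations: Mapping[str, np.ndarray],
    weights: Sequence[float] = (1.0, 1.0),
) -> LandmarkSet:
    """Build the full landmark set: J and O are located geometrically,
    M = (J + O) / 2, while A and the premolar apices X (and IOr/IOl, when
    present) are passed through from annotations."""
    points: Dict[str, np.ndarray] = {}
    if "A" not in annotations:
        raise PlannerError("missing A-point annotation")
    points["A"] = np.asarray(annotations["A"], dtype=float)
    for name in ("IOr", "IOl"):
        if name in annotations:
            points[name] = np.asarray(annotations[name], dtype=float)
    for side in SIDES:
        x_key = f"X_{side}"
        if x_key not in annotations:
            raise PlannerError(f"missing premolar apex (X) annotation for side '{side}'")
        region_key = f"R3_{side}"
        if region_key not in region_labels:
            raise PlannerError(f"missing zygoma region labels {region_key!r}")
        if side not in rim_polylines:
            raise PlannerError(f"missing orbital rim polyline for side '{side}'")
        J = locate_J(mesh, region_labels[region_key], weights)
        O = locate_O(rim_polylines[side], J)
        points[f"J_{side}"] = J
        points[f"O_{side}"] = O
        points[f"M_{side}"] = (J + O) / 2.0
        points[x_key] = np.asarray(annotations[x_key], dtype=float)
    return LandmarkSet(points)


def measure_segments(landmarks: LandmarkSet, side: str, subject_id: Optional[str] = None) -> SegmentMeasurement:
    """Lengths ``AX = ||A - X||`` and ``MX = ||M - X||`` plus the 3-point
    angle at the shared endpoint X."""
    for name in ("A", f"M_{side}", f"X_{side}"):
        if name not in landmarks:
            raise PlannerError(f"missing landmark {name!r}")
    A, M, X = landmarks["A"], landmarks[f"M_{side}"], landmarks[f"X_{side}"]
    return SegmentMeasurement(
        side=side,
        length_AX=float(np.linalg.norm(A - X)),
        length_MX=float(np.linalg.norm(M - X)),
        angle_deg=three_point_angle(A, X, M),
        subject_id=subject_id,
    )


_QUANTITIES = ("angle_deg", "length_AX", "length_MX")


@dataclass
class CuttingGuideTemplate:
    """Mean/SD cells for angle and segment lengths, per side and pooled."""

    cells: Dict[str, Dict[str, float]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group in ("left", "right", "pooled"):
            c = self.cells[group]
            rows.append(
                {
                    "group": group,
                    "n": c["n"],
                    **{f"{q}_{s}": c[f"{q}_{s}"] for q in _QUANTITIES for s in ("mean", "sd")},
                }
            )
        return pd.DataFrame(rows)


def pool_sides(measurements: Iterable[SegmentMeasurement]) -> CuttingGuideTemplate:
    """Per-side mean/SD (sample SD, n-1) and the side-pooled template.

    The pooled mean is taken over the concatenated left+right values, so for
    equal side counts it equals the arithmetic mean of the side means —
    doubling the effective sample size by ignoring side affiliation.
    """
    ms = list(measurements)
    by_side = {s: [m for m in ms if m.side == s] for s in SIDES}
    for s in SIDES:
        if not by_side[s]:
            raise PlannerError(f"no measurements for side '{s}'")

    def cell(values: np.ndarray) -> Dict[str, float]:
        return {
            "mean": float(np.mean(values)),
            "sd": float(np.std(values, ddof=1)) if len(values) > 1 else float("nan"),
        }

    cells: Dict[str, Dict[str, float]] = {}
    for group in ("left", "right", "pooled"):
        sel = by_side[group] if group in SIDES else by_side["left"] + by_side["right"]
        c: Dict[str, float] = {"n": len(sel)}
        for q in _QUANTITIES:
            stats = cell(np.array([getattr(m, q) for m in sel]))
            c[f"{q}_mean"] = stats["mean"]
            c[f"{q}_sd"] = stats["sd"]
        cells[group] = c
    return CuttingGuideTemplate(cells)
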