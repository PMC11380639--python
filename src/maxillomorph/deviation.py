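"""Signed surface deviation of a registered subject against reference regions.

Each labeled reference region is discretized into one sample per face
(centroid, outward normal, face area).  For every sample the closest point
on the subject surface gives the unsigned deviation; the sign comes from the
reference outward normal: *negative* when the subject lies in front of /
outside the reference (the classical blue of inspection false-color maps),
positive behind it.  Samples are valid only inside the measurement window
(default +/-5 mm) and only when the match does not land on an open boundary
of the subject mesh (missing surface - the grey, invalid areas).

Seven parameters summarize a region, area-weighted over valid samples:
Dmax, Dmin, Dmean, DSD (mm), AVD (mm^2, the valid area), and the integrals
ID = sum(a_i * d_i) and IAD = sum(a_i * |d_i|) (mm^3), with the identity
ID = Dmean * AVD holding by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import trimesh

from .geometry import SurfaceQuery

__all__ = [
    "RegionSamples",
    "DeviationField",
    "RegionDeviationSummary",
    "sample_region",
    "signed_deviation",
    "summarize_region",
    "false_color",
    "colored_mesh",
]


class DeviationError(ValueError):
    pass


@dataclass
class RegionSamples:
    """One sample per region face: centroid, unit outward normal, face area."""

    points: np.ndarray
    normals: np.ndarray
    area_weights: np.ndarray

    @property
    def total_area(self) -> float:
        return float(self.area_weights.sum())


@dataclass
class DeviationField:
    """Per-sample signed deviation (mm); invalid samples carry NaN."""

    d: np.ndarray
    valid: np.ndarray
    area_weights: np.ndarray
    window: float


@dataclass
class RegionDeviationSummary:
    Dmax: float
    Dmin: float
    Dmean: float
    DSD: float
    AVD: float
    ID: float
    IAD: float

    def as_dict(self) -> Dict[str, float]:
        return {
            "Dmax": self.Dmax,
            "Dmin": self.Dmin,
            "Dmean": self.Dmean,
            "DSD": self.DSD,
            "AVD": self.AVD,
            "ID": self.ID,
            "IAD": self.IAD,
        }


def sample_region(reference: trimesh.Trimesh, region_faces) -> RegionSamples:
    """Discretize a marked reference region: one sample per face."""
    region_faces = np.asarray(region_faces, dtype=int)
    if region_faces.size == 0:
        raise DeviationError("empty region")
    if region_faces.min() < 0 or region_faces.max() >= len(reference.faces):
        raise DeviationError("region face indices out of range")
    return RegionSamples(
        points=reference.triangles_center[region_faces].copy(),
        normals=reference.face_normals[region_faces].copy(),
        area_weights=reference.area_faces[region_faces].copy(),
    )


def signed_deviation(
    samples: RegionSamples,
    subject: trimesh.Trimesh,
    window: float = 5.0,
    query: Optional[SurfaceQuery] = None,
) -> DeviationField:
    """Signed closest-point deviation of the subject surface at each sample.

    The subject must already be registered into the reference frame.  Sign:
    negative when the closest subject point lies along the outward reference
    normal (subject in front of / outside the reference), positive behind.
    """
    if len(subject.faces) == 0:
        raise DeviationError("empty subject mesh")
    sq = query if query is not None else SurfaceQuery(subject)
    hits = sq.query(samples.points)
    delta = hits.point - samples.points
    outward = np.einsum("ij,ij->i", delta, samples.normals)
    d = np.where(outward > 0, -hits.distance, hits.distance)
    valid = (hits.distance <= window) & ~hits.on_boundary
    d = np.where(valid, d, np.nan)
    return DeviationField(d=d, valid=valid, area_weights=samples.area_weights.copy(), window=window)


def summarize_region(field: DeviationField) -> RegionDeviationSummary:
    """Area-weighted seven-parameter summary over the valid samples.

    A fully invalid region yields the designated empty summary: AVD = 0,
    ID = IAD = 0 and NaN distances (no comparison possible there).
    """
    m = field.valid
    if not m.any():
        nan = float("nan")
        return RegionDeviationSummary(nan, nan, nan, nan, 0.0, 0.0, 0.0)
    d = field.d[m]
    a = field.area_weights[m]
    avd = float(a.sum())
    dmean = float(np.sum(a * d) / avd)
    dsd = float(np.sqrt(np.sum(a * (d - dmean) ** 2) / avd))
    return RegionDeviationSummary(
        Dmax=float(d.max()),
        Dmin=float(d.min()),
        Dmean=dmean,
        DSD=dsd,
        AVD=avd,
        ID=dmean * avd,
        IAD=float(np.sum(a * np.abs(d))),
    )


_COLORS = {
    "green": np.array([0, 200, 0], dtype=float),
    "blue": np.array([0, 70, 255], dtype=float),
    "red": np.array([255, 40, 0], dtype=float),
    "grey": np.array([128, 128, 128], dtype=float),
}


def false_color(field: DeviationField, green_band: float = 1.0):
    """Inspection-style color labels and RGB values per sample.

    Grey marks invalid samples; |d| < green_band is green; beyond the band
    deviations ramp linearly into blue (in front) or red (behind) toward the
    window edge.
    """
    n = len(field.d)
    labels = np.full(n, "grey", dtype=object)
    rgb = np.tile(_COLORS["grey"], (n, 1))
    v = field.valid
    d = np.where(v, field.d, 0.0)
    span = max(field.window - green_band, 1e-12)
    frac = np.clip((np.abs(d) - green_band) / span, 0.0, 1.0)[:, None]
    labels[v & (np.abs(d) < green_band)] = "green"
    labels[v & (d <= -green_band)] = "blue"
    labels[v & (d >= green_band)] = "red"
    for name in ("green", "blue", "red"):
        sel = labels == name
        if name == "green":
            rgb[sel] = _COLORS["green"]
        else:
            rgb[sel] = (1 - frac[sel]) * _COLORS["green"] + frac[sel] * _COLORS[name]
    return labels, rgb.astype(np.uint8)


def colored_mesh(
    reference: trimesh.Trimesh,
    region_faces: Dict[str, np.ndarray],
    fields: Dict[str, DeviationField],
    green_band: float = 1.0,
) -> trimesh.Trimesh:
    """Reference mesh with per-face false colors for every computed region
    (unlabeled faces stay white) — the false-color figure analog."""
    mesh = reference.copy()
    colors = np.full((len(mesh.faces), 4), [255, 255, 255, 255], dtype=np.uint8)
    for key, field in fields.items():
        _, rgb = false_color(field, green_band)
        colors[np.asarray(region_faces[key], dtype=int), :3] = rgb
    mesh.visual.face_colors = colors
    return mesh
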