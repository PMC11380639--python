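"""Synthetic midface phantoms with known ground truth.

The reference phantom is a smooth, closed parametric head-sized ellipsoid
(semi-axes 70 x 60 x 80 mm; +X lateral, +Y anterior, +Z superior) standing in
for the reference skull: its anterior face carries labeled reconstructive
regions R1-R4 on each side (paranasal, facial sinus wall, zygomatic,
alveolar), an orbital-rim polyline per side, and the landmark seeds used for
alignment and planning.  A closed surface keeps the labeled regions a small
fraction (~7%) of the total area, as on a real skull, so surface-based
registration is anchored by unlabeled surface rather than by the regions
under measurement.  A smooth lateral-caudal protrusion inside each zygomatic
region makes the caudal-lateral score's maximum (the J landmark) unique and
reproducible under modest rotations.

Subject phantoms are the reference deformed by *known* effects - per-region
normal offsets (sex-conditioned), per-vertex noise, contiguous face dropout
in the alveolar region (edentulous / invalid areas), and a random rigid
misalignment - each recorded in a ground-truth table so every downstream
stage can be validated by recovery.

Sign convention: region offsets are stated on the deviation scale, where
*negative* means the subject lies in front of / outside the reference.  An
offset of -2 mm therefore displaces the region's vertices by +2 mm along the
outward surface normal, and is recovered downstream as Dmean of -2 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import trimesh
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .geometry import RigidTransform
from .planner import LandmarkSet, locate_J, locate_O

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "ReferencePhantom",
    "PhantomSubject",
    "make_reference_phantom",
    "synthesize_subject",
    "synthesize_cohort",
    "cohort_demographics",
]

REGIONS = ("R1", "R2", "R3", "R4")
SIDES = ("left", "right")

# ellipsoid semi-axes, mm (head-sized)
_A_LAT, _B_ANT, _C_VERT = 75.0, 65.0, 85.0

# region boxes in (|phi|, psi) degrees, phi = azimuth from anterior (+Y),
# psi = elevation; gaps of >= 8 degrees keep the per-region vertex sets
# disjoint at every supported resolution, so offsets never collide at
# shared vertices; box sizes give region areas close to the reported
# per-region valid areas (~350-650 mm^2)
_REGION_BOXES = {
    "R1": ((7.0, 16.0), (-16.0, 2.0)),
    "R2": ((26.0, 40.0), (-16.0, 6.0)),
    "R3": ((48.0, 64.0), (14.0, 32.0)),
    "R4": ((8.0, 34.0), (-52.0, -36.0)),
}

# zygoma protrusion: center (|phi|, psi), lateral-caudal amplitude mm, sigma deg
_ZYGOMA_BUMP = ((62.0, 16.0), 8.0, 6.0)

# icosphere subdivision per resolution class
_RESOLUTION_SUBDIV = {"coarse": 4, "medium": 5, "fine": 6}
_MIN_FACES = 500


class PhantomError(ValueError):
    pass


def _default_offset_means() -> Dict[str, Dict[str, float]]:
    # sex effect: males carry the paranasal/zygomatic outward offset
    # (negative on the deviation scale); magnitudes are config placeholders
    return {
        "male": {"R1": -1.5, "R2": 0.0, "R3": -1.5, "R4": 0.0},
        "female": {"R1": 0.0, "R2": 0.0, "R3": 0.0, "R4": 0.0},
    }


@dataclass
class PhantomSpec:
    """Cohort-generation parameters (all lengths mm, ages years)."""

    seed: int = 0
    n_subjects: int = 50
    region_offset_mean: Dict[str, Dict[str, float]] = field(default_factory=_default_offset_means)
    region_offset_sd: float = 0.1
    noise_sd: float = 0.05
    dropout_fraction: float = 0.1
    misalignment_mm: float = 3.0
    misalignment_deg: float = 3.0
    sex_ratio: float = 0.68
    age_range: Tuple[float, float] = (20.0, 89.0)
    landmark_jitter_sd: float = 0.0
    age_slope_mm_per_year: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise PhantomError("n_subjects must be >= 1")
        if not (0.0 <= self.dropout_fraction <= 1.0):
            raise PhantomError("dropout_fraction must lie in [0, 1]")
        for name in ("region_offset_sd", "noise_sd", "landmark_jitter_sd"):
            if getattr(self, name) < 0:
                raise PhantomError(f"{name} must be >= 0")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise PhantomError("sex_ratio must lie in [0, 1]")
        if self.age_range[1] < self.age_range[0]:
            raise PhantomError("age_range must be (min, max)")


@dataclass
class PhantomTruth:
    """Ground truth for one synthetic subject."""

    subject_id: str
    applied_transform: RigidTransform
    per_region_offset: Dict[str, float]
    dropout_area: float
    sex: str
    age: float


@dataclass
class ReferencePhantom:
    mesh: trimesh.Trimesh
    region_faces: Dict[str, np.ndarray]           # e.g. "R1_left" -> face indices
    landmarks: LandmarkSet
    rims: Dict[str, np.ndarray]                   # side -> (k, 3) polyline
    vertex_normals: np.ndarray                    # analytic outward normals

    @property
    def region_areas(self) -> Dict[str, float]:
        areas = self.mesh.area_faces
        return {k: float(areas[v].sum()) for k, v in self.region_faces.items()}


@dataclass
class PhantomSubject:
    subject_id: str
    mesh: trimesh.Trimesh
    region_faces: Dict[str, np.ndarray]
    landmarks: LandmarkSet
    rims: Dict[str, np.ndarray]
    truth: PhantomTruth


def _params_to_points(phi_deg, psi_deg) -> np.ndarray:
    phi = np.radians(np.asarray(phi_deg, dtype=float))
    psi = np.radians(np.asarray(psi_deg, dtype=float))
    return np.stack(
        [
            _A_LAT * np.sin(phi) * np.cos(psi),
            _B_ANT * np.cos(phi) * np.cos(psi),
            _C_VERT * np.sin(psi),
        ],
        axis=-1,
    )


def _analytic_normals(points: np.ndarray) -> np.ndarray:
    g = points / np.array([_A_LAT**2, _B_ANT**2, _C_VERT**2])
    return g / np.linalg.norm(g, axis=-1, keepdims=True)


def _subdivisions(resolution) -> int:
    if isinstance(resolution, str):
        try:
            s = _RESOLUTION_SUBDIV[resolution]
        except KeyError:
            raise PhantomError(
                f"unknown resolution {resolution!r}; use one of "
                f"{sorted(_RESOLUTION_SUBDIV)} or an integer icosphere subdivision"
            )
    else:
        s = int(resolution)
    if 20 * 4**s < _MIN_FACES:
        raise PhantomError(
            f"resolution gives {20 * 4 ** s} faces, below the coarse minimum of "
            f"{_MIN_FACES}; increase the subdivision level"
        )
    return s


def make_reference_phantom(resolution="medium") -> ReferencePhantom:
    """Build the labeled reference phantom.

    ``resolution`` is a vertex-count class ("coarse"/"medium"/"fine") or an
    integer icosphere subdivision level.
    """
    s = _subdivisions(resolution)
    unit = trimesh.creation.icosphere(subdivisions=s, radius=1.0)
    u = unit.vertices
    verts = u * np.array([_A_LAT, _B_ANT, _C_VERT])

    # parametric coordinates from the unit-sphere preimage
    def params_of(unit_dirs):
        psi = np.degrees(np.arcsin(np.clip(unit_dirs[:, 2], -1, 1)))
        phi = np.degrees(np.arctan2(unit_dirs[:, 0], unit_dirs[:, 1]))
        return phi, psi

    phi_v, psi_v = params_of(u)

    # zygoma protrusion: lateral-caudal bump inside each R3 box, making the
    # caudal-lateral extreme (J) unique; falloff is smooth (Gaussian in
    # angular distance on the parametric sphere)
    (b_phi, b_psi), b_amp, b_sig = _ZYGOMA_BUMP
    bump_w = np.zeros(len(verts))
    for sign in (-1.0, 1.0):
        d2 = (np.abs(phi_v) - b_phi) ** 2 + (psi_v - b_psi) ** 2
        w = np.exp(-d2 / (2 * b_sig**2))
        on_side = (np.sign(phi_v) == sign) | (phi_v == 0)
        dir_lat_caudal = np.array([sign, 0.0, -1.0]) / np.sqrt(2.0)
        verts = verts + (w * on_side)[:, None] * b_amp * dir_lat_caudal
        bump_w = np.maximum(bump_w, w * on_side)

    mesh = trimesh.Trimesh(vertices=verts, faces=unit.faces.copy(), process=False)
    # outward normals: analytic on the pristine ellipsoid, smoothed mesh
    # normals where the bump bends the surface
    normals = _analytic_normals(verts)
    blend = np.clip(bump_w / 1e-3, 0.0, 1.0)[:, None]
    vn = np.asarray(mesh.vertex_normals)
    normals = (1 - blend) * normals + blend * vn
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)

    centroid_dirs = u[mesh.faces].mean(axis=1)
    centroid_dirs /= np.linalg.norm(centroid_dirs, axis=1, keepdims=True)
    phi_c, psi_c = params_of(centroid_dirs)
    region_faces: Dict[str, np.ndarray] = {}
    for region, ((p_lo, p_hi), (s_lo, s_hi)) in _REGION_BOXES.items():
        for side, sign in (("left", -1.0), ("right", 1.0)):
            sel = (
                (sign * phi_c >= p_lo)
                & (sign * phi_c <= p_hi)
                & (psi_c >= s_lo)
                & (psi_c <= s_hi)
            )
            region_faces[f"{region}_{side}"] = np.flatnonzero(sel)

    vtree = cKDTree(verts)

    def nearest_vertex(phi0, psi0) -> int:
        return int(vtree.query(_params_to_points(phi0, psi0))[1])

    # orbital rim: mesh-vertex polyline along a dipping elevation profile;
    # the dip makes the "deepest point" (minimum z) unique -> IOr/IOl seed
    rims: Dict[str, np.ndarray] = {}
    io_points: Dict[str, np.ndarray] = {}
    for side, sign in (("left", -1.0), ("right", 1.0)):
        phis = np.linspace(8.0, 42.0, 40)
        psis = 38.0 - 6.0 * np.exp(-((phis - 25.0) ** 2) / (2 * 8.0**2))
        targets = _params_to_points(sign * phis, psis)
        ids = vtree.query(targets)[1]
        rim_ids = [int(ids[0])]
        for vid in ids[1:]:
            if int(vid) != rim_ids[-1]:
                rim_ids.append(int(vid))
        rim = verts[rim_ids]
        rims[side] = rim
        io_points[side] = rim[int(np.argmin(rim[:, 2]))].copy()

    points = {
        "A": verts[nearest_vertex(0.0, -30.0)].copy(),
        "IOr": io_points["right"],
        "IOl": io_points["left"],
    }
    for side, sign in (("left", -1.0), ("right", 1.0)):
        J = locate_J(mesh, region_faces[f"R3_{side}"])
        O = locate_O(rims[side], J)
        points[f"J_{side}"] = J
        points[f"O_{side}"] = O
        points[f"M_{side}"] = (J + O) / 2.0
        points[f"X_{side}"] = verts[nearest_vertex(sign * 26.0, -44.0)].copy()

    return ReferencePhantom(
        mesh=mesh,
        region_faces=region_faces,
        landmarks=LandmarkSet(points),
        rims=rims,
        vertex_normals=normals,
    )


def cohort_demographics(spec: PhantomSpec) -> Tuple[List[str], np.ndarray]:
    """Deterministic sex/age assignment for the whole cohort.

    Sex counts match ``sex_ratio`` up to rounding; ages are uniform over
    ``age_range``.
    """
    rng = np.random.default_rng([int(spec.seed), 11])
    n_male = int(round(spec.n_subjects * spec.sex_ratio))
    sexes = np.array(["male"] * n_male + ["female"] * (spec.n_subjects - n_male))
    rng.shuffle(sexes)
    ages = rng.uniform(spec.age_range[0], spec.age_range[1], spec.n_subjects)
    return list(sexes), ages


def _grow_patch(face_ids: np.ndarray, areas: np.ndarray, adjacency: np.ndarray,
                target_area: float, rng: np.random.Generator) -> List[int]:
    """Contiguous face patch of ~target_area grown by breadth-first search."""
    if target_area <= 0 or face_ids.size == 0:
        return []
    in_set = set(int(f) for f in face_ids)
    neighbors: Dict[int, List[int]] = {f: [] for f in in_set}
    for fa, fb in adjacency:
        fa, fb = int(fa), int(fb)
        if fa in in_set and fb in in_set:
            neighbors[fa].append(fb)
            neighbors[fb].append(fa)
    seed_face = int(rng.choice(face_ids))
    patch, seen, frontier = [], {seed_face}, [seed_face]
    acc = 0.0
    while frontier and acc < target_area:
        f = frontier.pop(0)
        patch.append(f)
        acc += areas[f]
        for nb in neighbors[f]:
            if nb not in seen:
                seen.add(nb)
                frontier.append(nb)
    return patch


def synthesize_subject(reference: ReferencePhantom, spec: PhantomSpec, subject_index: int) -> PhantomSubject:
    """One synthetic patient: reference + region offsets + noise + alveolar
    dropout, rigidly misaligned; every draw is recorded in the truth record."""
    if not (0 <= subject_index < spec.n_subjects):
        raise PhantomError("subject_index out of range for spec.n_subjects")
    sexes, ages = cohort_demographics(spec)
    sex, age = sexes[subject_index], float(ages[subject_index])
    rng = np.random.default_rng([int(spec.seed), 1000 + int(subject_index)])
    mesh = reference.mesh
    areas = mesh.area_faces

    age_term = spec.age_slope_mm_per_year * (age - float(np.mean(spec.age_range)))
    offsets = {
        r: float(rng.normal(spec.region_offset_mean[sex][r] + age_term, spec.region_offset_sd))
        for r in REGIONS
    }

    # per-region outward displacement; offsets use the deviation sign
    # convention (negative = outside the reference), hence the minus
    disp = np.zeros_like(mesh.vertices)
    for region in REGIONS:
        for side in SIDES:
            fids = reference.region_faces[f"{region}_{side}"]
            vids = np.unique(mesh.faces[fids])
            disp[vids] = -offsets[region] * reference.vertex_normals[vids]

    noise = (
        rng.normal(0.0, spec.noise_sd, mesh.vertices.shape)
        if spec.noise_sd > 0
        else np.zeros_like(mesh.vertices)
    )

    removed: List[int] = []
    if spec.dropout_fraction > 0:
        for side in SIDES:
            fids = reference.region_faces[f"R4_{side}"]
            target = spec.dropout_fraction * float(areas[fids].sum())
            removed.extend(_grow_patch(fids, areas, mesh.face_adjacency, target, rng))
    removed_arr = np.array(sorted(removed), dtype=int)
    dropout_area = float(areas[removed_arr].sum()) if removed_arr.size else 0.0

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = float(rng.uniform(-spec.misalignment_deg, spec.misalignment_deg))
    R = Rotation.from_rotvec(axis * np.radians(angle)).as_matrix()
    t = rng.uniform(-spec.misalignment_mm, spec.misalignment_mm, 3)
    T = RigidTransform(R, t)

    new_vertices = T.apply(mesh.vertices + disp + noise)
    keep = np.ones(len(mesh.faces), dtype=bool)
    keep[removed_arr] = False
    old_to_new = -np.ones(len(mesh.faces), dtype=int)
    old_to_new[keep] = np.arange(int(keep.sum()))
    subject_mesh = trimesh.Trimesh(vertices=new_vertices, faces=mesh.faces[keep], process=False)
    region_faces = {
        key: old_to_new[fids[keep[fids]]] for key, fids in reference.region_faces.items()
    }

    landmarks = reference.landmarks.transform(T)
    if spec.landmark_jitter_sd > 0:
        landmarks = LandmarkSet(
            {k: v + rng.normal(0.0, spec.landmark_jitter_sd, 3) for k, v in landmarks.points.items()}
        )
    rims = {side: T.apply(poly) for side, poly in reference.rims.items()}

    truth = PhantomTruth(
        subject_id=f"S{subject_index:03d}",
        applied_transform=T,
        per_region_offset=offsets,
        dropout_area=dropout_area,
        sex=sex,
        age=age,
    )
    return PhantomSubject(truth.subject_id, subject_mesh, region_faces, landmarks, rims, truth)


def truth_table(subjects: List[PhantomSubject]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        tr = s.truth
        rx, ry, rz = Rotation.from_matrix(tr.applied_transform.rotation).as_euler("xyz", degrees=True)
        rows.append(
            {
                "subject_id": tr.subject_id,
                "sex": tr.sex,
                "age": tr.age,
                **{f"offset_{r}": tr.per_region_offset[r] for r in REGIONS},
                "dropout_area": tr.dropout_area,
                "tx": tr.applied_transform.translation[0],
                "ty": tr.applied_transform.translation[1],
                "tz": tr.applied_transform.translation[2],
                "rx": rx,
                "ry": ry,
                "rz": rz,
            }
        )
    return pd.DataFrame(rows)


def synthesize_cohort(
    spec: PhantomSpec,
    reference: Optional[ReferencePhantom] = None,
    resolution="medium",
) -> Tuple[ReferencePhantom, List[PhantomSubject], pd.DataFrame]:
    """Full cohort: reference phantom, subject list and the truth table."""
    if reference is None:
        reference = make_reference_phantom(resolution)
    subjects = [synthesize_subject(reference, spec, i) for i in range(spec.n_subjects)]
    return reference, subjects, truth_table(subjects)
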