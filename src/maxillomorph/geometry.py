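"""Rigid transforms and exact closest-point queries on triangle surfaces.

Everything downstream (registration, surface deviation, landmark planning)
runs on two primitives: a proper rigid transform (rotation + translation,
no scaling, no reflection) and the exact closest point on a triangulated
surface.  The closest-point engine reports whether a query's nearest point
lies on an *open boundary* edge or vertex of the mesh: such matches have no
genuine surface correspondence (the true surface is missing there) and are
rejected by the deviation and registration stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree

__all__ = [
    "RigidTransform",
    "kabsch_align",
    "apply_transform",
    "rotation_angle_deg",
    "SurfaceQuery",
]

_ORTHO_TOL = 1e-8


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid map ``x -> R @ x + t`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise GeometryError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise GeometryError("reflection is not a rigid transform (det(R) < 0)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        if p.ndim == 1:
            return self.rotation @ p + self.translation
        return p @ self.rotation.T + self.translation

    def apply_mesh(self, mesh: trimesh.Trimesh) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.apply(mesh.vertices), faces=mesh.faces.copy(), process=False
        )

    def then(self, other: "RigidTransform") -> "RigidTransform":
        """Composite transform: apply ``self`` first, then ``other``."""
        return RigidTransform(
            other.rotation @ self.rotation,
            other.rotation @ self.translation + other.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def to_dict(self) -> dict:
        return {"R": self.rotation.tolist(), "t": self.translation.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["R"], dtype=float), np.asarray(d["t"], dtype=float))


def rotation_angle_deg(R: np.ndarray) -> float:
    """Geodesic rotation angle of an orthonormal matrix, in degrees."""
    c = (np.trace(np.asarray(R, dtype=float)) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def kabsch_align(source_points: np.ndarray, target_points: np.ndarray) -> RigidTransform:
    """Least-squares rigid alignment of paired points (Kabsch/Umeyama, no scaling).

    Minimizes ``sum ||R s_i + t - d_i||^2`` over proper rotations; exact when the
    correspondences are exact.  Rejects collinear configurations, for which the
    rotation about the common axis is undetermined.
    """
    s = np.asarray(source_points, dtype=float)
    d = np.asarray(target_points, dtype=float)
    if s.shape != d.shape or s.ndim != 2 or s.shape[0] < 3 or s.shape[1] != 3:
        raise GeometryError("need two equal-length lists of >= 3 points")
    cs, cd = s.mean(axis=0), d.mean(axis=0)
    s0, d0 = s - cs, d - cd
    # collinearity check: second singular value of the centered cloud
    sv = np.linalg.svd(s0, compute_uv=False)
    if s.shape[0] == 3:
        area = 0.5 * np.linalg.norm(np.cross(s[1] - s[0], s[2] - s[0]))
        if area <= 1e-6:
            raise GeometryError("alignment points are collinear (triangle area <= 1e-6 mm^2)")
    elif sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise GeometryError("alignment points are collinear")
    H = s0.T @ d0
    U, _, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, sign]) @ U.T
    return RigidTransform(R, cd - R @ cs)


def apply_transform(mesh_or_points, T: RigidTransform):
    """Apply a rigid transform to a mesh or an array of points (same kind out)."""
    if isinstance(mesh_or_points, trimesh.Trimesh):
        return T.apply_mesh(mesh_or_points)
    return T.apply(mesh_or_points)


def _closest_point_on_triangles(p, a, b, c):
    """Exact closest point on each triangle (a,b,c) to each point p.

    Vectorized Ericson-style region classification.  Returns the closest
    points and barycentric coordinates (w0, w1, w2) with exact zeros on
    clamped features, so edge/vertex hits are detectable without tolerance
    games.
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    n = p.shape[0]
    w1 = np.zeros(n)
    w2 = np.zeros(n)
    done = np.zeros(n, dtype=bool)

    def settle(mask, u, v):
        m = mask & ~done
        w1[m] = u[m] if isinstance(u, np.ndarray) else u
        w2[m] = v[m] if isinstance(v, np.ndarray) else v
        done[m] = True

    settle((d1 <= 0) & (d2 <= 0), 0.0, 0.0)          # vertex A
    settle((d3 >= 0) & (d4 <= d3), 1.0, 0.0)          # vertex B
    settle((d6 >= 0) & (d5 <= d6), 0.0, 1.0)          # vertex C
    with np.errstate(divide="ignore", invalid="ignore"):
        vc = d1 * d4 - d3 * d2
        t_ab = np.where(d1 != d3, d1 / (d1 - d3), 0.0)
        settle((vc <= 0) & (d1 >= 0) & (d3 <= 0), t_ab, 0.0)   # edge AB
        vb = d5 * d2 - d1 * d6
        t_ac = np.where(d2 != d6, d2 / (d2 - d6), 0.0)
        settle((vb <= 0) & (d2 >= 0) & (d6 <= 0), 0.0, t_ac)   # edge AC
        va = d3 * d6 - d5 * d4
        num = d4 - d3
        den = (d4 - d3) + (d5 - d6)
        t_bc = np.where(den != 0, num / den, 0.0)
        settle((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), 1.0 - t_bc, t_bc)  # edge BC
        denom = va + vb + vc
        u_in = np.where(denom != 0, vb / denom, 1.0 / 3.0)
        v_in = np.where(denom != 0, vc / denom, 1.0 / 3.0)
        settle(np.ones(n, dtype=bool), u_in, v_in)    # interior (or degenerate)

    closest = a + ab * w1[:, None] + ac * w2[:, None]
    w0 = 1.0 - w1 - w2
    return closest, np.stack([w0, w1, w2], axis=1)


@dataclass
class SurfaceHits:
    """Result of a closest-point query against a triangle surface."""

    distance: np.ndarray       # unsigned distance, mm
    point: np.ndarray          # closest point on the surface, (n, 3) mm
    face_index: np.ndarray     # triangle owning the closest point
    on_boundary: np.ndarray    # closest point lies on an open boundary edge/vertex


class SurfaceQuery:
    """Closest-point queries on a triangle mesh via a centroid KD-tree.

    The candidate search is provably exact in ``query``: every triangle whose
    true distance could beat the first guess has its centroid within
    ``d_guess + r_max`` of the query point, where ``r_max`` is the largest
    centroid-to-vertex radius over all faces.  ``query_approx`` skips the ball
    stage and checks only the k nearest centroids — adequate for dense
    correspondence search inside ICP, where queries sit near the surface.
    """

    def __init__(self, mesh: trimesh.Trimesh):
        if len(mesh.faces) == 0:
            raise GeometryError("empty mesh")
        self.triangles = mesh.triangles.astype(float)
        self.centroids = self.triangles.mean(axis=1)
        self.tree = cKDTree(self.centroids)
        self.r_max = float(
            np.sqrt(
                ((self.triangles - self.centroids[:, None, :]) ** 2).sum(axis=2).max()
            )
        )
        faces = mesh.faces
        edges = mesh.edges_sorted
        boundary_rows = trimesh.grouping.group_rows(edges, require_count=1)
        boundary_edges = set(map(tuple, edges[boundary_rows]))
        boundary_vertices = set(v for e in boundary_edges for v in e)
        # per-face flags: edge k connects face vertices (k, k+1 mod 3)
        n_f = len(faces)
        self._edge_boundary = np.zeros((n_f, 3), dtype=bool)
        self._vertex_boundary = np.zeros((n_f, 3), dtype=bool)
        if boundary_edges:
            for k in range(3):
                e = np.sort(faces[:, [k, (k + 1) % 3]], axis=1)
                self._edge_boundary[:, k] = [tuple(row) in boundary_edges for row in e]
                self._vertex_boundary[:, k] = [v in boundary_vertices for v in faces[:, k]]

    def _boundary_hit(self, face_idx: np.ndarray, bary: np.ndarray) -> np.ndarray:
        zero = bary <= 1e-12
        n = len(face_idx)
        out = np.zeros(n, dtype=bool)
        nz = zero.sum(axis=1)
        # two zero coords: closest point is the remaining vertex
        mv = nz == 2
        if mv.any():
            corner = np.argmin(zero[mv], axis=1)  # the non-zero one
            out[mv] = self._vertex_boundary[face_idx[mv], corner]
        # one zero coord w_i = 0: closest point is on the edge not containing vertex i,
        # i.e. face edge starting at vertex (i+1) mod 3
        me = nz == 1
        if me.any():
            i0 = np.argmax(zero[me], axis=1)
            out[me] = self._edge_boundary[face_idx[me], (i0 + 1) % 3]
        return out

    def _exact_to(self, points: np.ndarray, cand_faces: np.ndarray, cand_owner: np.ndarray):
        tri = self.triangles[cand_faces]
        cp, bary = _closest_point_on_triangles(
            points[cand_owner], tri[:, 0], tri[:, 1], tri[:, 2]
        )
        d = np.linalg.norm(cp - points[cand_owner], axis=1)
        return d, cp, bary

    def query_approx(self, points: np.ndarray, k: int = 8) -> SurfaceHits:
        points = np.asarray(points, dtype=float).reshape(-1, 3)
        k = min(k, len(self.centroids))
        n = len(points)
        _, idx = self.tree.query(points, k=k)
        idx = np.asarray(idx).reshape(n, k)
        owner = np.repeat(np.arange(n), k)
        cand = idx.ravel()
        d, cp, bary = self._exact_to(points, cand, owner)
        d2 = d.reshape(n, k)
        best = np.argmin(d2, axis=1)
        flat = np.arange(n) * k + best
        return self._pack(points, d[flat], cp[flat], cand[flat], bary[flat])

    def query(self, points: np.ndarray) -> SurfaceHits:
        points = np.asarray(points, dtype=float).reshape(-1, 3)
        n = len(points)
        _, i0 = self.tree.query(points)
        d0, _, _ = self._exact_to(points, np.asarray(i0).ravel(), np.arange(n))
        radius = d0 + self.r_max + 1e-9
        lists = self.tree.query_ball_point(points, radius)
        lengths = np.array([len(l) for l in lists])
        cand = np.concatenate([np.asarray(l, dtype=int) for l in lists])
        owner = np.repeat(np.arange(n), lengths)
        d, cp, bary = self._exact_to(points, cand, owner)
        offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]])
        dmin = np.minimum.reduceat(d, offsets)
        winner = d <= dmin[owner] + 0.0
        # first winner per query point
        _, first = np.unique(owner[winner], return_index=True)
        flat = np.flatnonzero(winner)[first]
        return self._pack(points, d[flat], cp[flat], cand[flat], bary[flat])

    def _pack(self, points, d, cp, fi, bary) -> SurfaceHits:
        return SurfaceHits(
            distance=d,
            point=cp,
            face_index=fi,
            on_boundary=self._boundary_hit(fi, bary),
        )
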