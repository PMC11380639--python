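"""Subject-to-reference alignment: 3-point landmark fit + local best fit.

The workflow mirrors optical-inspection practice: an initial Kabsch alignment
on three anatomically constant landmarks (A-point and the two inferior
orbital rim points) brings the subject into the reference frame, then a
trimmed point-to-point ICP ("local best fit") refines it.  Only sample
points whose closest reference-surface match lies within a fixed radius
(default 4.0 mm) participate in each iteration, and matches that land on an
open mesh boundary are rejected as having no genuine correspondence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
import trimesh

from .geometry import (
    RigidTransform,
    SurfaceQuery,
    apply_transform,
    kabsch_align,
    rotation_angle_deg,
)

__all__ = ["ICPResult", "local_best_fit", "kabsch_align", "apply_transform"]


class RegistrationError(ValueError):
    pass


@dataclass
class ICPResult:
    """Refined transform plus per-iteration diagnostics."""

    transform: RigidTransform
    rms_history: List[float]       # post-update RMS per iteration, mm
    init_rms: float                # init transform's RMS over the final correspondence set
    final_rms: float
    n_iterations: int
    n_correspondences: int


def local_best_fit(
    moving: trimesh.Trimesh,
    fixed: trimesh.Trimesh,
    init: RigidTransform,
    radius: float = 4.0,
    tol: float = 1e-6,
    max_iterations: int = 100,
) -> ICPResult:
    """Trimmed point-to-point ICP from ``init``; returns the composed transform.

    Samples are the moving mesh's face centroids.  Correspondences are exact
    closest points on the fixed surface, re-trimmed each iteration to those
    within ``radius`` (and off the fixed mesh's open boundary).  Stops when
    the RMS change drops below ``tol`` mm or after ``max_iterations``.
    """
    if len(moving.faces) == 0 or len(fixed.faces) == 0:
        raise RegistrationError("empty mesh")
    samples = moving.triangles_center
    sq = SurfaceQuery(fixed)

    T = init
    rms_history: List[float] = []
    prev_rms = None
    mask = None
    for iteration in range(max_iterations):
        hits = sq.query_approx(T.apply(samples))
        mask = (hits.distance <= radius) & ~hits.on_boundary
        n_corr = int(mask.sum())
        if n_corr < 3:
            raise RegistrationError(
                f"only {n_corr} correspondences within {radius} mm of the fixed surface — "
                "gross misalignment; refine the initial alignment"
            )
        T = kabsch_align(samples[mask], hits.point[mask])
        resid = np.linalg.norm(T.apply(samples[mask]) - hits.point[mask], axis=1)
        rms = float(np.sqrt(np.mean(resid**2)))
        rms_history.append(rms)
        if prev_rms is not None and abs(prev_rms - rms) < tol:
            break
        prev_rms = rms

    # residuals of the init transform over the final correspondence set
    final_pts = T.apply(samples[mask])
    final_hits = sq.query_approx(final_pts)
    final_resid = np.linalg.norm(final_pts - final_hits.point, axis=1)
    init_pts = init.apply(samples[mask])
    init_hits = sq.query_approx(init_pts)
    init_resid = np.linalg.norm(init_pts - init_hits.point, axis=1)
    return ICPResult(
        transform=T,
        rms_history=rms_history,
        init_rms=float(np.sqrt(np.mean(init_resid**2))),
        final_rms=float(np.sqrt(np.mean(final_resid**2))),
        n_iterations=len(rms_history),
        n_correspondences=int(mask.sum()),
    )


def register_subject(
    subject_landmarks,
    reference_landmarks,
    subject_mesh: trimesh.Trimesh,
    reference_mesh: trimesh.Trimesh,
    radius: float = 4.0,
    tol: float = 1e-6,
    max_iterations: int = 100,
) -> ICPResult:
    """3-point Kabsch on (A, IOr, IOl) followed by local best fit."""
    init = kabsch_align(
        subject_landmarks.alignment_triplet(), reference_landmarks.alignment_triplet()
    )
    return local_best_fit(
        subject_mesh, reference_mesh, init, radius=radius, tol=tol, max_iterations=max_iterations
    )
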