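#!/usr/bin/env python
"""Run the full analysis pipeline on the simulated cohort and check the
registration stage against the known ground truth.

Re-synthesizes the same cohort (same spec and seed as 01), registers every
subject to the reference by 3-point alignment + 4 mm local best fit,
computes the per-region deviation fields and the segment measurements, and
writes all tables under results/run/.  Then compares every recovered
transform with the inverse of the transform the generator actually applied.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from maxillomorph.geometry import RigidTransform, rotation_angle_deg
from maxillomorph.phantom import PhantomSpec
from maxillomorph.pipeline import RunConfig, run_pipeline

SEED = 20
ROOT = Path(__file__).resolve().parents[1]

run_dir = run_pipeline(
    RunConfig(
        out_dir=ROOT / "results" / "run",
        seed=SEED,
        phantom=PhantomSpec(),
        resolution="coarse",
        write_meshes=False,
    )
)
print(f"pipeline complete: {run_dir}")

truth = pd.read_csv(run_dir / "truth.csv", comment="#")
rows = []
for _, t in truth.iterrows():
    T_applied = RigidTransform(
        Rotation.from_euler("xyz", [t.rx, t.ry, t.rz], degrees=True).as_matrix(),
        np.array([t.tx, t.ty, t.tz]),
    )
    rec = json.loads((run_dir / "transforms" / f"{t.subject_id}.json").read_text())
    T_rec = RigidTransform(np.array(rec["R"]), np.array(rec["t"]))
    inv = T_applied.inverse()
    rows.append(
        {
            "subject_id": t.subject_id,
            "translation_error_mm": float(np.linalg.norm(T_rec.translation - inv.translation)),
            "rotation_error_deg": rotation_angle_deg(T_rec.rotation @ T_applied.rotation),
        }
    )
rec_df = pd.DataFrame(rows)
rec_df.to_csv(ROOT / "results" / "registration_recovery.csv", index=False)
print(
    "registration recovery over %d subjects (offsets, noise and dropout present): "
    "median %.3f mm / %.3f deg, max %.3f mm / %.3f deg"
    % (
        len(rec_df),
        rec_df.translation_error_mm.median(),
        rec_df.rotation_error_deg.median(),
        rec_df.translation_error_mm.max(),
        rec_df.rotation_error_deg.max(),
    )
)
print("(residual error reflects the injected region offsets pulling the "
      "surface fit, not a registration defect: noiseless rigid-only subjects "
      "recover to < 1e-3 mm, see the test suite)")
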