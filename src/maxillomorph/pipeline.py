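"""End-to-end cohort analysis: phantom (or files) -> registration ->
deviation -> segment planning -> cohort statistics.

One ``run_pipeline`` call produces, under the output directory: per-subject
rigid transforms, registered meshes and false-color deviation meshes; the
per-region deviation summary table; the per-subject segment measurements;
the cohort-level region table (mean +/- SD per region and parameter, sides
pooled), the mean-value cutting-guide template, demographics, and a
statistics report.  Subjects whose alveolar-region (R4) valid area is an
extreme IQR outlier are excluded from the R4 cohort summary — those are the
edentulous / incomplete comparisons — and every exclusion is logged.
Identical configuration and seed reproduce byte-identical tables; the
configuration hash is recorded in every CSV header.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd

from . import io as mio
from .deviation import colored_mesh, sample_region, signed_deviation, summarize_region
from .geometry import SurfaceQuery
from .phantom import (
    REGIONS,
    SIDES,
    PhantomSpec,
    make_reference_phantom,
    synthesize_cohort,
)
from .planner import construct_landmarks, measure_segments, pool_sides
from .registration import register_subject
from .stats import StatsError, chi_square, elbow_select, iqr_outliers, kmeans_1d, welch_t

__all__ = [
    "RunConfig",
    "run_pipeline",
    "make_report",
    "percent",
    "format_count_percent",
    "age_range_years",
    "truncate",
]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """All knobs of a run.  Measurement parameters default to the published
    protocol values: HU window 226-48,060, 4.0 mm best-fit radius, +/-5 mm
    deviation window, 1 mm green band, 1.5x/3x IQR fences."""

    out_dir: Union[str, Path]
    seed: int = 0
    # phantom mode
    phantom: Optional[PhantomSpec] = None
    resolution: Union[str, int] = "coarse"
    # file mode
    reference_mesh: Optional[str] = None
    regions: Optional[str] = None
    rims: Optional[str] = None
    reference_landmarks: Optional[str] = None
    subject_meshes: List[str] = field(default_factory=list)
    subject_landmarks: List[str] = field(default_factory=list)
    # protocol parameters
    hu_min: float = 226.0
    hu_max: float = 48060.0
    icp_radius: float = 4.0
    icp_tol: float = 1e-6
    icp_max_iterations: int = 100
    window: float = 5.0
    green_band: float = 1.0
    iqr_normal: float = 1.5
    iqr_extreme: float = 3.0
    k_clusters: int = 2
    k_max: int = 6
    write_meshes: bool = True

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d["out_dir"] = None  # the output location does not define the run
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def truncate(x: float, decimals: int = 2) -> float:
    """Truncate toward zero at the given number of decimals."""
    f = 10.0**decimals
    return np.trunc(x * f) / f


def percent(part: float, total: float) -> float:
    return 100.0 * part / total


def format_count_percent(count: int, total: int) -> str:
    return f"{count} ({percent(count, total):.0f}%)"


def age_range_years(age_min: float, age_max: float) -> float:
    return age_max - age_min


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False)


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _load_file_cohort(config: RunConfig):
    """File-mode inputs: reference bundle + per-subject meshes/landmarks."""
    for name in ("reference_mesh", "regions", "rims", "reference_landmarks"):
        value = getattr(config, name)
        if value is None or not Path(value).exists():
            raise PipelineError(f"missing input '{name}'")
    if not config.subject_meshes or len(config.subject_meshes) != len(config.subject_landmarks):
        raise PipelineError("subject_meshes and subject_landmarks must be equal-length, non-empty lists")
    reference = {
        "mesh": mio.load_mesh(config.reference_mesh),
        "region_faces": mio.load_regions(config.regions),
        "rims": mio.load_rims(config.rims),
        "landmarks": mio.load_landmarks(config.reference_landmarks),
    }
    subjects = []
    for i, (mp, lp) in enumerate(zip(config.subject_meshes, config.subject_landmarks)):
        subjects.append(
            {
                "subject_id": f"S{i:03d}",
                "mesh": mio.load_mesh(mp),
                "landmarks": mio.load_landmarks(lp),
                "region_faces": None,
                "rims": None,
            }
        )
    return reference, subjects, None


def run_pipeline(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()

    # ---- inputs -----------------------------------------------------------
    if config.phantom is not None:
        spec = dataclasses.replace(config.phantom, seed=config.seed)
        ref_bundle, phantom_subjects, truth = synthesize_cohort(spec, resolution=config.resolution)
        reference = {
            "mesh": ref_bundle.mesh,
            "region_faces": ref_bundle.region_faces,
            "rims": ref_bundle.rims,
            "landmarks": ref_bundle.landmarks,
        }
        subjects = [
            {
                "subject_id": s.subject_id,
                "mesh": s.mesh,
                "landmarks": s.landmarks,
                "region_faces": s.region_faces,
                "rims": s.rims,
            }
            for s in phantom_subjects
        ]
        demographics = truth[["subject_id", "sex", "age"]].copy()
        _write_csv(truth, out / "truth.csv", cfg_hash)
    else:
        reference, subjects, _ = _load_file_cohort(config)
        demographics = None

    ref_mesh = reference["mesh"]
    ref_samples = {key: sample_region(ref_mesh, fids) for key, fids in reference["region_faces"].items()}

    # ---- per-subject stages ----------------------------------------------
    dev_rows, seg_rows = [], []
    mesh_dir = out / "subjects"
    for sub in subjects:
        sid = sub["subject_id"]
        try:
            icp = register_subject(
                sub["landmarks"],
                reference["landmarks"],
                sub["mesh"],
                ref_mesh,
                radius=config.icp_radius,
                tol=config.icp_tol,
                max_iterations=config.icp_max_iterations,
            )
        except Exception as e:
            raise PipelineError(f"registration failed for subject {sid}: {e}") from e
        T = icp.transform
        registered = T.apply_mesh(sub["mesh"])
        mio.save_transform(T, out / "transforms" / f"{sid}.json")

        try:
            sq = SurfaceQuery(registered)
            fields = {}
            for key, samples in ref_samples.items():
                field_ = signed_deviation(samples, registered, window=config.window, query=sq)
                fields[key] = field_
                summ = summarize_region(field_)
                region, side = key.split("_")
                dev_rows.append(
                    {
                        "subject_id": sid,
                        "region": region,
                        "side": side,
                        "region_area": samples.total_area,
                        **summ.as_dict(),
                    }
                )
        except Exception as e:
            raise PipelineError(f"deviation failed for subject {sid}: {e}") from e

        try:
            lm_reg = sub["landmarks"].transform(T)
            if sub["region_faces"] is not None:
                annotations = {
                    "A": lm_reg["A"],
                    "IOr": lm_reg["IOr"],
                    "IOl": lm_reg["IOl"],
                    "X_left": lm_reg["X_left"],
                    "X_right": lm_reg["X_right"],
                }
                rims_reg = {s: T.apply(p) for s, p in sub["rims"].items()}
                lm_full = construct_landmarks(registered, sub["region_faces"], rims_reg, annotations)
            else:
                lm_full = lm_reg  # file mode: landmarks supplied externally
            for side in SIDES:
                m = measure_segments(lm_full, side, subject_id=sid)
                seg_rows.append(
                    {
                        "subject_id": sid,
                        "side": side,
                        "length_AX_mm": m.length_AX,
                        "length_MX_mm": m.length_MX,
                        "angle_deg": m.angle_deg,
                    }
                )
        except Exception as e:
            raise PipelineError(f"planning failed for subject {sid}: {e}") from e

        if config.write_meshes:
            mio.save_mesh(registered, mesh_dir / f"{sid}_registered.stl")
            mio.save_mesh(
                colored_mesh(ref_mesh, reference["region_faces"], fields, config.green_band),
                mesh_dir / f"{sid}_deviation.ply",
            )

    dev = pd.DataFrame(dev_rows)
    seg = pd.DataFrame(seg_rows)
    _write_csv(dev, out / "region_summaries.csv", cfg_hash)
    _write_csv(seg, out / "measurements.csv", cfg_hash)

    # ---- cohort level -----------------------------------------------------
    excluded = _r4_avd_exclusions(dev, config)
    cohort = _cohort_region_table(dev, excluded)
    _write_csv(cohort, out / "region_cohort_summary.csv", cfg_hash)

    measurements = [
        measure_segments_from_row(row) for row in seg.to_dict("records")
    ]
    template = pool_sides(measurements)
    _write_csv(template.to_frame(), out / "template.csv", cfg_hash)

    if demographics is not None:
        _write_csv(demographics, out / "demographics.csv", cfg_hash)

    stats_report = _cohort_stats(dev, demographics, excluded, config)
    (out / "stats_report.json").write_text(json.dumps(stats_report, indent=1, default=str))

    log = {
        "config_hash": cfg_hash,
        "seed": config.seed,
        "n_subjects": len(subjects),
        "excluded_r4_avd_extreme": sorted(excluded),
        "python": platform.python_version(),
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
    }
    (out / "log.json").write_text(json.dumps(log, indent=1))
    return out


def measure_segments_from_row(row: dict):
    from .planner import SegmentMeasurement

    return SegmentMeasurement(
        side=row["side"],
        length_AX=row["length_AX_mm"],
        length_MX=row["length_MX_mm"],
        angle_deg=row["angle_deg"],
        subject_id=row.get("subject_id"),
    )


def _r4_avd_exclusions(dev: pd.DataFrame, config: RunConfig) -> set:
    """Subjects whose R4 valid area is an extreme IQR outlier on either side."""
    r4 = dev[dev.region == "R4"]
    if len(r4) < 4:
        return set()
    flags = iqr_outliers(r4.AVD.to_numpy(), config.iqr_normal, config.iqr_extreme).flags
    return set(r4.subject_id.to_numpy()[flags == "extreme"])


def _cohort_region_table(dev: pd.DataFrame, excluded: set) -> pd.DataFrame:
    """Mean +/- SD of each parameter per region, sides pooled as samples."""
    rows = []
    for region, grp in dev.groupby("region", sort=True):
        if region == "R4" and excluded:
            grp = grp[~grp.subject_id.isin(excluded)]
        row = {"region": region, "n_values": len(grp)}
        for p in ("Dmax", "Dmin", "Dmean", "DSD", "AVD", "ID", "IAD"):
            vals = grp[p].dropna()
            row[f"{p}_mean"] = float(vals.mean())
            row[f"{p}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def _cohort_stats(dev, demographics, excluded, config: RunConfig) -> dict:
    """Outlier counts, sex/age association tests and clustering per region
    and parameter, mirroring the cohort analysis plan."""
    report: Dict[str, dict] = {}
    if demographics is None:
        return {"note": "no demographics available (file mode)"}
    demo = demographics.set_index("subject_id")
    for region in REGIONS:
        sel = dev[dev.region == region]
        if region == "R4" and excluded:
            sel = sel[~sel.subject_id.isin(excluded)]
        region_report = {}
        for param in ("Dmean", "AVD", "ID", "IAD"):
            entry: Dict[str, object] = {}
            vals = sel[param].dropna()
            subj = sel.subject_id[vals.index]
            try:
                fl = iqr_outliers(vals.to_numpy(), config.iqr_normal, config.iqr_extreme)
                entry["n_normal_outliers"] = int((fl.flags == "normal").sum())
                entry["n_extreme_outliers"] = int((fl.flags == "extreme").sum())
                extreme_subjects = set(subj.to_numpy()[fl.flags == "extreme"])
                has_extreme = np.array([s in extreme_subjects for s in demo.index])
                sexes = demo.sex.to_numpy()
                table = [
                    [int(((sexes == "male") & has_extreme).sum()), int(((sexes == "male") & ~has_extreme).sum())],
                    [int(((sexes == "female") & has_extreme).sum()), int(((sexes == "female") & ~has_extreme).sum())],
                ]
                try:
                    chi = chi_square(table)
                    entry["sex_chi2"] = {"statistic": chi.statistic, "df": chi.df, "p": chi.p_value}
                except StatsError as e:
                    entry["sex_chi2"] = f"not available: {e}"
                ages = demo.age.to_numpy()
                if has_extreme.sum() >= 2 and (~has_extreme).sum() >= 2:
                    w = welch_t(ages[has_extreme], ages[~has_extreme])
                    entry["age_welch"] = {"statistic": w.statistic, "df": w.df, "p": w.p_value}
                else:
                    entry["age_welch"] = "not available: fewer than 2 subjects per outlier group"
            except StatsError as e:
                entry["outliers"] = f"not available: {e}"
            if param in ("Dmean", "ID", "IAD"):
                try:
                    cl = kmeans_1d(vals.to_numpy(), config.k_clusters, seed=config.seed)
                    comp = {}
                    for c in range(cl.k):
                        members = subj.to_numpy()[cl.assignments == c]
                        sexes_c = demo.sex.loc[list(dict.fromkeys(members))]
                        comp[f"cluster_{c}"] = {
                            "center": float(cl.centers[c]),
                            "n_values": int((cl.assignments == c).sum()),
                            "n_male_subjects": int((sexes_c == "male").sum()),
                            "n_female_subjects": int((sexes_c == "female").sum()),
                        }
                    entry["kmeans"] = comp
                    entry["elbow_k"] = int(elbow_select(vals.to_numpy(), config.k_max, seed=config.seed))
                except StatsError as e:
                    entry["kmeans"] = f"not available: {e}"
            region_report[param] = entry
        report[region] = region_report
    return report


def make_report(run_dir) -> str:
    """Human-readable cohort report (demographics, region table, template)."""
    run_dir = Path(run_dir)
    missing = [
        name
        for name in ("region_cohort_summary.csv", "template.csv", "log.json")
        if not (run_dir / name).exists()
    ]
    if missing:
        raise PipelineError(f"incomplete run: missing {', '.join(missing)}")
    log = json.loads((run_dir / "log.json").read_text())
    lines = [
        "Cohort analysis report",
        "======================",
        f"run config hash: {log['config_hash']}  seed: {log['seed']}",
        "",
    ]
    demo_path = run_dir / "demographics.csv"
    if demo_path.exists():
        demo = _read_csv(demo_path)
        n = len(demo)
        n_male = int((demo.sex == "male").sum())
        ages = demo.age
        lines += [
            f"Patients (n = {n})",
            f"  age mean (median): {ages.mean():.2f} ({ages.median():.2f})",
            f"  age range (min-max): {age_range_years(ages.min(), ages.max()):.0f} ({ages.min():.0f}-{ages.max():.0f})",
            f"  age SD: {ages.std(ddof=1):.2f}",
            f"  sex male: {format_count_percent(n_male, n)}",
            f"  sex female: {format_count_percent(n - n_male, n)}",
            "",
        ]
    cohort = _read_csv(run_dir / "region_cohort_summary.csv")
    lines.append("Region parameters, mean (SD), sides pooled:")
    for _, row in cohort.iterrows():
        cells = ", ".join(
            f"{p} {row[f'{p}_mean']:.2f} ({row[f'{p}_sd']:.2f})"
            for p in ("Dmax", "Dmin", "Dmean", "DSD", "AVD", "ID", "IAD")
        )
        lines.append(f"  {row.region}: {cells}")
    if log.get("excluded_r4_avd_extreme"):
        lines.append(
            f"  (R4 summary excludes extreme AVD outliers: {', '.join(log['excluded_r4_avd_extreme'])})"
        )
    lines.append("")
    tpl = _read_csv(run_dir / "template.csv")
    lines.append("Cutting-guide template (two-segment reconstruction):")
    for _, row in tpl.iterrows():
        lines.append(
            f"  {row.group} (n={row.n}): angle {row.angle_deg_mean:.2f} deg (SD {row.angle_deg_sd:.2f}), "
            f"AX {row.length_AX_mean:.2f} mm (SD {row.length_AX_sd:.2f}), "
            f"MX {row.length_MX_mean:.2f} mm (SD {row.length_MX_sd:.2f})"
        )
    text = "\n".join(lines) + "\n"
    (run_dir / "report.txt").write_text(text)
    return text
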