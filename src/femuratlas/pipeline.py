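"""End-to-end orchestration: simulate, calibrate, frame, cloud, sample, fit.

The pipeline ties the stage modules together for batch runs over a case
directory, carries a configuration hash into every output for
provenance, and logs per-stage counts. It is a thin layer: every
scientific step lives in the stage modules and is callable directly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

from . import calibration as cal
from . import cloud as cl
from . import cortical as ctx
from . import frame as fr
from . import regression as reg
from . import sampling as smp
from . import synthetic as syn
from .core import Volume, dump_json, load_json

__all__ = ["RunConfig", "run_simulate", "run_full", "StageError"]

logger = logging.getLogger("femuratlas")


class StageError(RuntimeError):
    def __init__(self, stage: str, case_id: str | None, message: str):
        self.stage = stage
        self.case_id = case_id
        super().__init__(
            f"[{stage}]{' case ' + case_id if case_id else ''}: {message}")


@dataclass
class RunConfig:
    """All tunables of a pipeline run; every output embeds its hash."""

    out_dir: str = "atlas_run"
    n_donors: int = 6
    paired: bool = True
    seed: int = 0
    age_range: tuple[float, float] = (20.0, 94.0)
    bmi_range: tuple[float, float] = (17.0, 40.0)
    female_fraction: float = 0.34
    subject_scales: tuple[float, ...] = (0.9, 1.0, 1.1)
    noise_sd_hu: float = 0.0
    use_truth_frames: bool = False
    area_increase_threshold: float = fr.AREA_INCREASE_THRESHOLD
    radial_spacing_mm: float = cl.RADIAL_SPACING_MM
    reference_sphere_radius_mm: float = smp.REFERENCE_SPHERE_RADIUS_MM
    min_voxels_per_sphere: int = smp.MIN_VOXELS_PER_SPHERE
    removal_fraction: float = smp.REMOVAL_FRACTION
    alpha: float = reg.SIGNIFICANCE_ALPHA
    min_cases_per_fit: int = reg.MIN_CASES_PER_FIT

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for name in ("area_increase_threshold", "radial_spacing_mm",
                     "reference_sphere_radius_mm", "removal_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir")   # provenance covers parameters, not paths
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("age_range", "bmi_range", "subject_scales"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def _case_scale(config: RunConfig, index: int) -> float:
    scales = config.subject_scales
    return float(scales[index % len(scales)])


def run_simulate(config: RunConfig) -> Path:
    """Generate the synthetic dataset on disk.

    Emits population.csv, per-case HU volumes with the embedded
    calibration rod, femur masks, periosteal/endosteal meshes, and a
    truth JSON per case; plus the run config and its hash.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = syn.sample_population(
        config.n_donors, config.age_range, config.bmi_range,
        config.female_fraction, seed=config.seed, paired=config.paired)
    records = syn.apply_exclusion_criteria(records)
    base = syn.FemurPhantomParams(noise_sd=config.noise_sd_hu)
    maps_by_scale: dict[float, syn.EffectMaps] = {}
    geo_by_scale: dict[float, syn.FemurGeometry] = {}
    rows = []
    for i, rec in enumerate(records):
        donor_index = i // 2 if config.paired else i
        scale = _case_scale(config, donor_index)
        if scale not in geo_by_scale:
            params = base.scaled(scale)
            geo_by_scale[scale] = syn.build_geometry(params)
            maps_by_scale[scale] = syn.make_effect_maps(params)
        params = geo_by_scale[scale].params
        hu, mask, truth = syn.build_femur(
            params, rec, maps_by_scale[scale],
            seed=config.seed * 100003 + i, geometry=geo_by_scale[scale])
        hu = syn.embed_phantom(hu, params=params,
                               seed=config.seed * 100003 + i)
        cid = rec.id
        hu.save_nifti(out / f"{cid}_hu.nii.gz")
        mask.save_nifti(out / f"{cid}_mask.nii.gz")
        truth.outer_mesh.export(out / f"{cid}_outer.stl")
        truth.inner_mesh.export(out / f"{cid}_inner.stl")
        truth_d = truth.frame_dict()
        truth_d["scale"] = scale
        truth_d["config_hash"] = config.config_hash
        truth_d["effect_maps"] = maps_by_scale[scale].description
        dump_json(truth_d, out / f"{cid}_truth.json")
        rows.append((cid, rec.age, rec.bmi, rec.sex, rec.side, scale))
        logger.info("simulate: wrote case %s (scale %.2f)", cid, scale)
    pd.DataFrame(rows, columns=["id", "age", "bmi", "sex", "side", "scale"]
                 ).to_csv(out / "population.csv", index=False)
    config.to_yaml(out / "run_config.yaml")
    dump_json({"config_hash": config.config_hash,
               "n_cases": len(records)}, out / "provenance.json")
    logger.info("simulate: %d cases complete", len(records))
    return out


def _load_case(out: Path, cid: str):
    try:
        hu = Volume.load_nifti(out / f"{cid}_hu.nii.gz")
        mask = Volume.load_nifti(out / f"{cid}_mask.nii.gz")
        outer = trimesh.load(out / f"{cid}_outer.stl", process=False)
        inner = trimesh.load(out / f"{cid}_inner.stl", process=False)
        truth = load_json(out / f"{cid}_truth.json")
    except Exception as e:
        raise StageError("load_geometry", cid, str(e)) from e
    return hu, mask, outer, inner, truth


def _truth_frame(truth: dict, mask: Volume, outer, config: RunConfig
                 ) -> fr.FemurFrame:
    from .core import Axis
    neck = Axis(truth["neck_axis"]["point"], truth["neck_axis"]["direction"])
    shaft = Axis(truth["shaft_axis"]["point"], truth["shaft_axis"]["direction"])
    neck, shaft = fr.refine_axes(neck, shaft)
    plane, _ = fr.place_cutting_plane(outer, neck,
                                      threshold=config.area_increase_threshold)
    lt = np.array(truth["lesser_trochanter"])
    v_above = fr.volume_above_lt(mask, shaft, lt)
    crop, _ = fr.crop_distal(outer, shaft, lt, v_above)
    return fr.FemurFrame(
        head_center=np.array(truth["head_center"]),
        head_radius=float(truth["head_radius"]),
        neck_axis=neck, shaft_axis=shaft, lesser_trochanter=lt,
        cutting_plane=plane, crop_level=crop)


def run_full(config: RunConfig) -> dict:
    """Run the complete analysis over a simulated case directory.

    Stages: per-slice calibration, sagittal mirroring of left cases,
    frame estimation, reference-locked cloud construction, sphere
    sampling, point filtering, per-sex atlas fits with ROI tables, and
    cortical quadrant tables. Returns a report dict (also written to
    report.json) with per-stage counts; any stage failure raises a
    :class:`StageError` naming the stage and case.
    """
    out = Path(config.out_dir)
    pop = pd.read_csv(out / "population.csv")
    subjects = [syn.SubjectRecord(str(r.id), float(r.age), float(r.bmi),
                                  str(r.sex), str(r.side))
                for r in pop.itertuples()]
    layout = syn.ChamberLayout()
    report = {"config_hash": config.config_hash, "stages": {}}
    cases = {}
    for rec in subjects:
        cid = rec.id
        hu, mask, outer, inner, truth = _load_case(out, cid)
        mask = _embed_mask(mask, hu)
        try:
            calibrated, lines = cal.calibrate_volume(hu, mask, layout)
        except Exception as e:
            raise StageError("calibration", cid, str(e)) from e
        n_missing = sum(1 for ln in lines if ln is None)
        if rec.side == "left":
            calibrated = cal.CalibratedVolume(
                bmd=fr.mirror_left(calibrated.bmd),
                femur_mask=fr.mirror_left(calibrated.femur_mask))
            mask = fr.mirror_left(mask)
            outer = fr.mirror_left(outer)
            inner = fr.mirror_left(inner)
            truth = _mirror_truth(truth)
        try:
            if config.use_truth_frames:
                frame = _truth_frame(truth, mask, outer, config)
            else:
                frame = fr.estimate_frame(
                    outer, mask,
                    area_threshold=config.area_increase_threshold)
        except Exception as e:
            raise StageError("coordinate_frame", cid, str(e)) from e
        frame.to_json(out / f"{cid}_frame.json")
        cases[cid] = dict(rec=rec, calibrated=calibrated, mask=mask,
                          outer=outer, inner=inner, frame=frame,
                          missing_lines=n_missing)
    report["stages"]["calibration"] = {
        "cases": len(cases),
        "slices_without_line": int(sum(c["missing_lines"]
                                       for c in cases.values()))}

    # reference geometry: the first unit-scale case, else the first case
    ref_id = next((str(r.id) for r in pop.itertuples()
                   if abs(float(r.scale) - 1.0) < 1e-9),
                  str(pop.iloc[0]["id"]))
    ref = cases[ref_id]
    cloud_cfg = cl.CloudConfig(radial_spacing_mm=config.radial_spacing_mm)
    ref_cloud = cl.build_cloud(ref["frame"], ref["outer"], ref["mask"],
                               config=cloud_cfg, case_id=ref_id)
    v_ref = fr.volume_above_lt(ref["mask"], ref["frame"].shaft_axis,
                               ref["frame"].lesser_trochanter)
    samples, radii, ray_tables = [], {}, []
    for cid, c in cases.items():
        try:
            if cid == ref_id:
                cloud = ref_cloud
            else:
                cloud = cl.build_cloud(c["frame"], c["outer"], c["mask"],
                                       config=ref_cloud.config, case_id=cid)
            cloud.to_csv(out / f"{cid}_cloud.csv")
            v = fr.volume_above_lt(c["mask"], c["frame"].shaft_axis,
                                   c["frame"].lesser_trochanter)
            radius = smp.sphere_radius(
                v, v_ref, config.reference_sphere_radius_mm)
            radii[cid] = radius
            samples.append(smp.sample_case(cloud, c["calibrated"], radius, cid))
        except Exception as e:
            raise StageError("point_cloud", cid, str(e)) from e
        try:
            ray_tables.append(ctx.compute_radii(
                c["frame"], c["outer"], c["inner"], case_id=cid))
        except Exception as e:
            raise StageError("cortical_geometry", cid, str(e)) from e
    matrix = smp.build_sample_matrix(samples)
    matrix.to_csv(out / "sample_matrix.csv", index=False)
    retained, removed = smp.filter_points(matrix, config.removal_fraction)
    report["stages"]["sampling"] = {
        "points_retained": len(retained), "points_removed": len(removed),
        "sphere_radius_range_mm": [min(radii.values()), max(radii.values())]}
    rays = pd.concat(ray_tables, ignore_index=True)
    rays.to_csv(out / "cortical_rays.csv", index=False)

    atlas_counts, roi_rows, quad_frames = {}, [], []
    for sex in ("female", "male"):
        n_sex = sum(1 for r in subjects if r.sex == sex)
        if n_sex < config.min_cases_per_fit:
            atlas_counts[sex] = 0
            continue
        try:
            atlas = reg.fit_atlas(matrix, subjects, sex, retained=retained,
                                  min_cases=config.min_cases_per_fit)
            atlas.to_csv(out / f"atlas_{sex}.csv")
            atlas_counts[sex] = len(atlas.point_ids)
            for roi in reg.DEFAULT_ROIS.values():
                roi_rows.append(reg.roi_regression(
                    matrix, subjects, roi, sex,
                    min_cases=config.min_cases_per_fit))
            for region in ("neck", "shaft"):
                quad_frames.append(ctx.quadrant_summary(
                    rays, subjects, sex, region,
                    min_cases=config.min_cases_per_fit))
        except Exception as e:
            raise StageError("regression_atlas", None, f"sex={sex}: {e}") from e
    if roi_rows:
        pd.DataFrame(roi_rows).to_csv(out / "roi_table.csv", index=False)
    if quad_frames:
        pd.concat(quad_frames, ignore_index=True).to_csv(
            out / "quadrant_table.csv", index=False)
    report["stages"]["atlas"] = {"points_fitted": atlas_counts}
    dump_json(report, out / "report.json")
    logger.info("run_full complete: %s", report["stages"])
    return report


def _embed_mask(mask: Volume, hu: Volume) -> Volume:
    """Zero-pad the femur mask onto the (larger) scan grid of ``hu``."""
    if mask.shape == hu.shape and np.allclose(mask.origin, hu.origin):
        return mask
    off = np.rint((mask.origin - hu.origin) / hu.spacing).astype(int)
    if np.any(off < 0) or np.any(off + mask.shape > hu.shape):
        raise ValueError("femur mask grid does not fit inside the scan grid")
    data = np.zeros(hu.shape, dtype=mask.data.dtype)
    data[off[0]:off[0] + mask.shape[0],
         off[1]:off[1] + mask.shape[1],
         off[2]:off[2] + mask.shape[2]] = mask.data
    return Volume(data, hu.spacing.copy(), hu.origin.copy())


def _mirror_truth(truth: dict) -> dict:
    def mv(v):
        v = list(map(float, v))
        v[0] = -v[0]
        return v
    t = dict(truth)
    t["head_center"] = mv(truth["head_center"])
    t["lesser_trochanter"] = mv(truth["lesser_trochanter"])
    for ax in ("neck_axis", "shaft_axis"):
        t[ax] = {"point": mv(truth[ax]["point"]),
                 "direction": mv(truth[ax]["direction"])}
    return t
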