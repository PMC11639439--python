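"""Cortical radii and thickness profiles along the 12 directions.

For each direction (phi, z) of the coordinate system, rays from the
governing axis are intersected with both the periosteal (outer) and
endosteal (inner) cortical meshes; the inner and outer radii are the
distances from the axis to the respective farthest intersection, and
the cortical thickness their difference. The femoral head is excluded:
sub-voxel cortices there defeat endosteal segmentation, so the analysis
covers neck and shaft stations only. The endosteal surface is an input
contract (here supplied by the phantom generator's ground truth; in a
clinical pipeline by an external cortical-bone-mapping tool).

Quadrant summaries average thickness over the standard angular sets —
anterior (60-120 deg), inferior/medial (150-210 deg), posterior
(240-300 deg), superior/lateral (330-30 deg) — over neck stations
z in [9, 12] and diaphyseal stations z in [33, 38], then regress the
per-case averages on age and BMI; relative differences are slopes as a
percentage of the predicted thickness at age 20 / BMI 25.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .cloud import (N_DIRECTIONS, ZStation, discretize_axes,
                    generate_directions, lt_azimuth)
from .frame import FemurFrame
from .raycast import TriangleRayCaster
from .regression import MIN_CASES_PER_FIT, fit_point
from .synthetic import SubjectRecord

__all__ = [
    "CorticalRay",
    "QUADRANTS",
    "NECK_SUMMARY_Z",
    "SHAFT_SUMMARY_Z",
    "compute_radii",
    "fit_cortical_regression",
    "quadrant_summary",
    "interpolate_profile",
]

# phi indices per anatomical quadrant (30-degree direction labels)
QUADRANTS: dict[str, tuple[int, ...]] = {
    "anterior": (2, 3, 4),           # 60, 90, 120 deg
    "inferior_medial": (5, 6, 7),    # 150, 180, 210 deg
    "posterior": (8, 9, 10),         # 240, 270, 300 deg
    "superior_lateral": (11, 0, 1),  # 330, 0, 30 deg
}
NECK_SUMMARY_Z = tuple(range(9, 13))
SHAFT_SUMMARY_Z = tuple(range(33, 39))
NECK_CORTICAL_Z = tuple(range(9, 13))    # head stations excluded
SHAFT_CORTICAL_Z = tuple(range(13, 39))


@dataclass(frozen=True)
class CorticalRay:
    z_index: int
    phi_index: int
    inner_radius: float
    outer_radius: float
    thickness: float
    valid: bool


def compute_radii(
    frame: FemurFrame,
    outer_mesh,
    inner_mesh,
    z_range: Sequence[int] | None = None,
    case_id: str = "",
    stations: Sequence[ZStation] | None = None,
) -> pd.DataFrame:
    """Inner/outer radii and thickness per (phi, z) direction.

    ``z_range`` defaults to the neck band plus the whole shaft side; the
    head is never profiled. A ray missing either mesh, or hitting the
    inner mesh beyond the outer one (non-physical), is flagged invalid.
    Precomputed ``stations`` (e.g. for analytic test geometries whose
    meshes carry no head) bypass the axis discretization.
    """
    if z_range is None:
        z_range = tuple(NECK_CORTICAL_Z) + tuple(SHAFT_CORTICAL_Z)
    zset = set(int(z) for z in z_range)
    if stations is None:
        stations = discretize_axes(frame, outer_mesh)
        phi_lt = lt_azimuth(frame, stations)
    else:
        phi_lt = None
    outer_caster = TriangleRayCaster(outer_mesh)
    inner_caster = TriangleRayCaster(inner_mesh)
    rows = []
    for st in stations:
        if st.z_index not in zset:
            continue
        dirs, _ = generate_directions(
            st, frame,
            lt_azimuth_deg=phi_lt if (phi_lt is not None
                                      and st.region == "shaft_side")
            else None)
        tri_out = outer_caster.plane_triangles(st.origin, st.normal)
        tri_in = inner_caster.plane_triangles(st.origin, st.normal)
        for phi in range(N_DIRECTIONS):
            r_out = outer_caster.farthest_hit(st.origin, dirs[phi], tri_out)
            r_in = inner_caster.farthest_hit(st.origin, dirs[phi], tri_in)
            valid = (r_out is not None and r_in is not None
                     and 0 < r_in <= r_out)
            rows.append((st.z_index, phi,
                         r_in if r_in is not None else np.nan,
                         r_out if r_out is not None else np.nan,
                         (r_out - r_in) if valid else np.nan,
                         valid))
    df = pd.DataFrame(rows, columns=[
        "z_index", "phi_index", "inner_radius", "outer_radius",
        "thickness", "valid"])
    df["case_id"] = case_id
    return df


def fit_cortical_regression(
    rays: pd.DataFrame,
    subjects: Sequence[SubjectRecord],
    sex: str,
    min_cases: int = MIN_CASES_PER_FIT,
) -> pd.DataFrame:
    """Per-direction linear age/BMI fits of radii and thickness.

    One row per (z, phi) and measure in {inner_radius, outer_radius,
    thickness}: slope_age, slope_bmi, intercept, p-values, n. Only that
    sex's cases and valid rays enter each fit; directions with too few
    cases are skipped.
    """
    subj = {r.id: r for r in subjects if r.sex == sex}
    sub = rays[rays["case_id"].isin(subj) & rays["valid"]]
    out = []
    for (z, phi), g in sub.groupby(["z_index", "phi_index"], sort=True):
        ages = np.array([subj[c].age for c in g["case_id"]])
        bmis = np.array([subj[c].bmi for c in g["case_id"]])
        for measure in ("inner_radius", "outer_radius", "thickness"):
            try:
                pr = fit_point(g[measure], ages, bmis, min_cases=min_cases)
            except ValueError:
                continue
            out.append((int(z), int(phi), measure, pr.q, pr.s, pr.b,
                        pr.p_age, pr.p_bmi, pr.n_cases))
    return pd.DataFrame(out, columns=[
        "z_index", "phi_index", "measure", "slope_age", "slope_bmi",
        "intercept", "p_age", "p_bmi", "n_cases"])


def quadrant_summary(
    rays: pd.DataFrame,
    subjects: Sequence[SubjectRecord],
    sex: str,
    region: str = "neck",
    min_cases: int = MIN_CASES_PER_FIT,
    baseline: tuple[float, float] = (20.0, 25.0),
) -> pd.DataFrame:
    """Quadrant-averaged thickness evolution (relative-difference table).

    Thickness is averaged per case over the quadrant's (phi, z) member
    rays, then regressed on age and BMI; relative differences divide
    the slopes by the predicted thickness at the baseline covariates.
    """
    zset = NECK_SUMMARY_Z if region == "neck" else SHAFT_SUMMARY_Z
    subj = {r.id: r for r in subjects if r.sex == sex}
    sub = rays[rays["case_id"].isin(subj) & rays["valid"]
               & rays["z_index"].isin(zset)]
    rows = []
    for name, phis in QUADRANTS.items():
        q = sub[sub["phi_index"].isin(phis)]
        if q.empty:
            raise ValueError(f"quadrant {name!r} empty in region {region!r}")
        means = q.groupby("case_id")["thickness"].mean()
        ages = np.array([subj[c].age for c in means.index])
        bmis = np.array([subj[c].bmi for c in means.index])
        pr = fit_point(means.to_numpy(), ages, bmis, min_cases=min_cases)
        base = pr.predict(*baseline)
        rows.append((region, name, sex, float(means.mean()), pr.q, pr.s,
                     pr.p_age, pr.p_bmi, base,
                     100.0 * pr.q / base, 100.0 * pr.s / base,
                     pr.n_cases))
    return pd.DataFrame(rows, columns=[
        "region", "quadrant", "sex", "mean_thickness", "slope_age",
        "slope_bmi", "p_age", "p_bmi", "baseline_thickness",
        "rel_diff_age_pct", "rel_diff_bmi_pct", "n_cases"])


def interpolate_profile(values: Sequence[float], n_samples: int = 360
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Closed periodic cubic spline through the 12 angular values.

    Returns (angles_deg, interpolated values) over a full turn; the
    curve passes exactly through every control value at its 30-degree
    angle and matches value and derivatives at 0/360.
    """
    v = np.asarray(values, dtype=float)
    if len(v) != N_DIRECTIONS:
        raise ValueError(f"expected {N_DIRECTIONS} values, got {len(v)}")
    if not np.all(np.isfinite(v)):
        raise ValueError("profile values must be finite")
    angles = np.arange(N_DIRECTIONS + 1) * 30.0
    spline = CubicSpline(angles, np.append(v, v[0]), bc_type="periodic")
    grid = np.linspace(0.0, 360.0, n_samples)
    return grid, spline(grid)
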