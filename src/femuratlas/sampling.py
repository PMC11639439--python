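"""Sphere-averaged BMD at every cloud point, with dismissal rules.

Each cloud point receives the mean calibrated density over voxels whose
centers lie within a sphere around it, clipped to the femur mask (the
sphere may straddle the surface). The sphere radius scales with femur
size (cube root of the volume above the lesser trochanter) so the
fractional bone coverage of the cloud is size-independent; it is 1.5 mm
for a femur of reference size. Spheres landing outside the femur or
catching fewer than five mask voxels are dismissed; points dismissed in
more than 20 % of cases are removed from the atlas altogether.

Voxel membership is by voxel-center-in-sphere with no partial-voxel
weighting, which makes the five-voxel minimum an exact count and the
mean exactly reproducible by brute-force enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import CalibratedVolume
from .cloud import AtlasPointCloud

__all__ = [
    "SampleResult",
    "REFERENCE_SPHERE_RADIUS_MM",
    "MIN_VOXELS_PER_SPHERE",
    "REMOVAL_FRACTION",
    "sphere_radius",
    "sphere_average",
    "sample_case",
    "build_sample_matrix",
    "filter_points",
    "sphere_overlap_fraction",
]

REFERENCE_SPHERE_RADIUS_MM = 1.5
MIN_VOXELS_PER_SPHERE = 5
REMOVAL_FRACTION = 0.20


@dataclass(frozen=True)
class SampleResult:
    point_id: tuple[int, int, int]
    mean_bmd: float
    voxel_count: int
    dismissed: bool
    case_id: str = ""
    out_of_bounds: bool = False


def sphere_radius(
    volume_above_lt: float,
    reference_volume: float,
    reference_radius: float = REFERENCE_SPHERE_RADIUS_MM,
) -> float:
    """Size-scaled averaging-sphere radius in mm.

    radius = reference_radius * (V / V_ref)^(1/3), so the sphere volume
    tracks the femur volume and cloud coverage is size-invariant.
    """
    if volume_above_lt <= 0 or reference_volume <= 0:
        raise ValueError("femur volumes must be positive")
    return float(reference_radius * (volume_above_lt / reference_volume) ** (1.0 / 3.0))


def sphere_average(
    calibrated: CalibratedVolume,
    center: np.ndarray,
    radius: float,
    point_id: tuple[int, int, int] = (0, 0, 0),
    case_id: str = "",
) -> SampleResult:
    """Mean BMD over mask voxels with centers inside the sphere.

    Dismissed when fewer than MIN_VOXELS_PER_SPHERE qualifying voxels
    remain (including the sphere-entirely-outside case); a center
    outside the volume bounds is dismissed with an out-of-bounds flag.
    """
    if radius <= 0:
        raise ValueError("sphere radius must be positive")
    vol = calibrated.bmd
    center = np.asarray(center, dtype=float)
    lo_w = vol.origin
    hi_w = vol.origin + vol.spacing * (np.array(vol.shape) - 1)
    if np.any(center < lo_w - 1e-9) or np.any(center > hi_w + 1e-9):
        return SampleResult(point_id, float("nan"), 0, True, case_id,
                            out_of_bounds=True)
    lo = np.floor((center - radius - vol.origin) / vol.spacing).astype(int)
    hi = np.ceil((center + radius - vol.origin) / vol.spacing).astype(int) + 1
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, vol.shape)
    if np.any(lo >= hi):
        return SampleResult(point_id, float("nan"), 0, True, case_id)
    sub_bmd = vol.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub_mask = np.asarray(calibrated.femur_mask.data)[
        lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] > 0
    axes = [vol.origin[d] + vol.spacing[d] * np.arange(lo[d], hi[d])
            for d in range(3)]
    dx = axes[0] - center[0]
    dy = axes[1] - center[1]
    dz = axes[2] - center[2]
    dist2 = (dx[:, None, None] ** 2 + dy[None, :, None] ** 2
             + dz[None, None, :] ** 2)
    inside = (dist2 <= radius ** 2) & sub_mask
    count = int(np.count_nonzero(inside))
    if count < MIN_VOXELS_PER_SPHERE:
        return SampleResult(point_id, float("nan"), count, True, case_id)
    return SampleResult(point_id, float(sub_bmd[inside].mean()), count,
                        False, case_id)


def sample_case(
    cloud: AtlasPointCloud,
    calibrated: CalibratedVolume,
    radius: float,
    case_id: str = "",
) -> pd.DataFrame:
    """One row of the case-by-point sample matrix, as a long DataFrame.

    Points flagged outside the femur are dismissed without sampling.
    Returns columns point_id fields, mean_bmd, voxel_count, dismissed.
    """
    rows = []
    pts = cloud.points
    pos = pts[["x", "y", "z"]].to_numpy()
    ids = pts[["z_index", "phi_index", "radial_ordinal"]].to_numpy()
    inside = pts["inside_bone"].to_numpy()
    for i in range(len(pts)):
        pid = tuple(int(v) for v in ids[i])
        if not inside[i] or not np.all(np.isfinite(pos[i])):
            rows.append((*pid, float("nan"), 0, True))
            continue
        res = sphere_average(calibrated, pos[i], radius, pid, case_id)
        rows.append((*pid, res.mean_bmd, res.voxel_count, res.dismissed))
    df = pd.DataFrame(rows, columns=[
        "z_index", "phi_index", "radial_ordinal", "mean_bmd",
        "voxel_count", "dismissed"])
    df["case_id"] = case_id
    return df


def build_sample_matrix(case_samples: list[pd.DataFrame]) -> pd.DataFrame:
    """Stack per-case long tables; columns checked for correspondence."""
    if not case_samples:
        raise ValueError("no cases")
    ref_ids = case_samples[0][["z_index", "phi_index", "radial_ordinal"]]
    for df in case_samples[1:]:
        if not ref_ids.equals(df[["z_index", "phi_index", "radial_ordinal"]]):
            raise ValueError("case sample point index sets differ")
    return pd.concat(case_samples, ignore_index=True)


def filter_points(
    matrix: pd.DataFrame,
    threshold: float = REMOVAL_FRACTION,
) -> tuple[list[tuple[int, int, int]], list[tuple[int, int, int]]]:
    """Split points into retained and removed by dismissal fraction.

    A point is removed when its sphere was dismissed in strictly more
    than ``threshold`` of the cases.
    """
    if matrix.empty:
        raise ValueError("empty sample matrix")
    grp = matrix.groupby(["z_index", "phi_index", "radial_ordinal"])["dismissed"]
    frac = grp.mean()
    removed = [tuple(int(v) for v in idx) for idx in frac[frac > threshold].index]
    retained = [tuple(int(v) for v in idx) for idx in frac[frac <= threshold].index]
    return retained, removed


def sphere_overlap_fraction(spacing_mm: float, radius: float) -> float:
    """Fractional volume overlap of two spheres a center-distance apart.

    Diagnostic for neighboring cloud points: lens volume of two equal
    spheres with centers ``spacing_mm`` apart, as a fraction of one
    sphere's volume (0 when the spacing exceeds the diameter).
    """
    d = spacing_mm
    r = radius
    if d >= 2 * r:
        return 0.0
    lens = np.pi * (2 * r - d) ** 2 * (d ** 2 + 4 * d * r) / (12.0 * d)
    return float(lens / (4.0 / 3.0 * np.pi * r ** 3))
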