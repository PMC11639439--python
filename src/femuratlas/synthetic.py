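"""Synthetic proximal-femur phantoms with known ground truth.

The phantom geometry is a smooth union of analytic primitives — head
sphere, neck frustum (round cone), shaft cylinder and two trochanteric
ellipsoid bumps — evaluated as a signed-distance field (SDF) on a regular
voxel grid. Surfaces (periosteal and endosteal) come from marching cubes
of the same field, so mesh and mask are consistent by construction.

The trabecular density field is linear in the subject covariates,

    BMD(x) = age * q(x) + BMI * s(x) + b(x),

with smooth, spatially varying slope fields ``q`` (per year) and ``s``
(per BMI point) and intercept ``b``; the cortical shell elevates ``b``.
Voxels are emitted in Hounsfield units via a linear HU model with
optional additive Gaussian noise, mimicking a calibrated QCT acquisition.

Template dimensions are fabricated plausible values for an adult right
femur; they are not measurements of any specific population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import trimesh
from skimage.measure import marching_cubes

from .core import Axis, Volume

__all__ = [
    "SubjectRecord",
    "FemurPhantomParams",
    "EffectMaps",
    "GroundTruth",
    "ChamberLayout",
    "sample_population",
    "apply_exclusion_criteria",
    "build_geometry",
    "build_femur",
    "make_effect_maps",
    "build_phantom_slab",
    "embed_phantom",
]


# --------------------------------------------------------------------------
# subjects

@dataclass(frozen=True)
class SubjectRecord:
    """One scanned femur case: donor covariates plus the imaged side."""

    id: str
    age: float
    bmi: float
    sex: str  # "female" | "male"
    side: str  # "left" | "right"

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.side not in ("left", "right"):
            raise ValueError(f"unknown side {self.side!r}")


def sample_population(
    n: int,
    age_range: tuple[float, float] = (20.0, 94.0),
    bmi_range: tuple[float, float] = (17.0, 40.0),
    female_fraction: float = 0.34,
    seed: int = 0,
    paired: bool = False,
) -> list[SubjectRecord]:
    """Draw a reproducible donor population.

    Ages are uniform over ``age_range``; BMI is a truncated normal
    (mean 25.5, sd 4.5) clipped to ``bmi_range``, matching the skewed
    but bounded spread of adult autopsy cohorts. With ``paired=True``
    each of the ``n`` donors contributes both femurs (two records).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if age_range[0] > age_range[1] or bmi_range[0] > bmi_range[1]:
        raise ValueError("empty covariate range")
    rng = np.random.default_rng(seed)
    ages = rng.uniform(age_range[0], age_range[1], size=n)
    bmis = np.clip(rng.normal(25.5, 4.5, size=n), bmi_range[0], bmi_range[1])
    sexes = np.where(rng.random(n) < female_fraction, "female", "male")
    sides = np.where(rng.random(n) < 0.5, "left", "right")
    records = []
    for i in range(n):
        donor = f"D{i:04d}"
        if paired:
            for side in ("left", "right"):
                records.append(
                    SubjectRecord(f"{donor}{side[0].upper()}", float(ages[i]),
                                  float(bmis[i]), str(sexes[i]), side)
                )
        else:
            records.append(
                SubjectRecord(donor, float(ages[i]), float(bmis[i]),
                              str(sexes[i]), str(sides[i]))
            )
    return records


def apply_exclusion_criteria(records: Sequence[SubjectRecord]) -> list[SubjectRecord]:
    """Drop donors below age 20, with unknown age, or with BMI outside [16, 40].

    The BMI bounds are exclusive exclusions (BMI < 16 or BMI > 40 is
    removed; exactly 16 or 40 is retained). Non-finite covariates count
    as unknown. Input order is preserved.
    """
    kept = []
    for r in records:
        if r.age is None or not np.isfinite(r.age) or r.age < 20:
            continue
        if r.bmi is None or not np.isfinite(r.bmi) or r.bmi < 16 or r.bmi > 40:
            continue
        kept.append(r)
    return kept


# --------------------------------------------------------------------------
# geometry parameters

@dataclass(frozen=True)
class FemurPhantomParams:
    """Parametric right-femur template plus voxelization and HU model.

    Linear dimensions are mm. The template frame has +z superior
    (proximal), +x lateral, +y anterior; medial is -x. Left femurs are
    produced by sagittal mirroring of this right-side template.
    """

    head_radius: float = 23.0
    neck_radius: float = 13.0
    neck_base_radius: float = 17.0
    neck_length: float = 48.0
    neck_shaft_angle: float = 130.0  # degrees, medial angle
    shaft_radius: float = 14.5
    shaft_length: float = 90.0
    # trochanter bump ellipsoids: (semi-axes), center offsets from junction
    gt_semiaxes: tuple[float, float, float] = (11.0, 10.0, 15.0)
    gt_offset: tuple[float, float, float] = (11.0, 0.0, 7.0)
    lt_semiaxes: tuple[float, float, float] = (9.0, 8.0, 11.0)
    lt_radial_offset: float = 3.0     # beyond shaft surface, medial-posterior
    lt_drop: float = 20.0             # below junction
    blend: float = 7.0                # smooth-min radius
    cortical_thickness_map: dict = field(default_factory=lambda: {
        "head": 1.0, "neck_superior": 1.8, "neck_inferior": 3.2,
        "trochanter": 2.2, "shaft": 4.5,
    })
    voxel_spacing: tuple[float, float, float] = (1.1, 1.1, 0.7)
    margin: float = 6.0
    hu_slope: float = 0.8             # HU per (mg/cm^3)
    hu_intercept: float = -20.0       # HU
    noise_sd: float = 0.0             # HU
    soft_tissue_bmd: float = 30.0     # background pseudo-density outside bone

    def __post_init__(self):
        for name in ("head_radius", "neck_radius", "neck_base_radius",
                     "neck_length", "shaft_radius", "shaft_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 90.0 < self.neck_shaft_angle < 180.0:
            raise ValueError("neck_shaft_angle must lie in (90, 180) degrees")
        if np.any(np.asarray(self.voxel_spacing) <= 0):
            raise ValueError("voxel_spacing must be positive")

    def scaled(self, factor: float) -> "FemurPhantomParams":
        """Uniformly scale all linear template dimensions by ``factor``."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        f = float(factor)
        return replace(
            self,
            head_radius=self.head_radius * f,
            neck_radius=self.neck_radius * f,
            neck_base_radius=self.neck_base_radius * f,
            neck_length=self.neck_length * f,
            shaft_radius=self.shaft_radius * f,
            shaft_length=self.shaft_length * f,
            gt_semiaxes=tuple(a * f for a in self.gt_semiaxes),
            gt_offset=tuple(a * f for a in self.gt_offset),
            lt_semiaxes=tuple(a * f for a in self.lt_semiaxes),
            lt_radial_offset=self.lt_radial_offset * f,
            lt_drop=self.lt_drop * f,
            blend=self.blend * f,
            cortical_thickness_map={k: v * f for k, v in
                                    self.cortical_thickness_map.items()},
        )


@dataclass(frozen=True)
class EffectMaps:
    """Ground-truth spatial fields of the linear age/BMI density model.

    ``q_field``/``s_field``/``b_field`` map (N, 3) template-frame
    positions to mg/cm^3-per-year, mg/cm^3-per-BMI-point and mg/cm^3
    intercept values; ``residual_sd`` is the case-to-case scatter around
    the linear model in density units.
    """

    q_field: Callable[[np.ndarray], np.ndarray]
    s_field: Callable[[np.ndarray], np.ndarray]
    b_field: Callable[[np.ndarray], np.ndarray]
    residual_sd: float = 30.0
    description: dict = field(default_factory=dict)


@dataclass
class GroundTruth:
    """Everything the analysis later has to estimate, known exactly."""

    outer_mesh: trimesh.Trimesh
    inner_mesh: trimesh.Trimesh
    head_center: np.ndarray
    head_radius: float
    neck_axis: Axis
    shaft_axis: Axis
    lesser_trochanter: np.ndarray
    effect_maps: EffectMaps | None
    side: str = "right"
    warnings: list = field(default_factory=list)

    def frame_dict(self) -> dict:
        return {
            "head_center": self.head_center,
            "head_radius": self.head_radius,
            "neck_axis": {"point": self.neck_axis.point,
                          "direction": self.neck_axis.direction},
            "shaft_axis": {"point": self.shaft_axis.point,
                           "direction": self.shaft_axis.direction},
            "lesser_trochanter": self.lesser_trochanter,
            "side": self.side,
            "warnings": list(self.warnings),
        }


# --------------------------------------------------------------------------
# signed distance primitives (vectorized over (N, 3) point arrays)

def _sd_sphere(p, center, r):
    return np.linalg.norm(p - center, axis=-1) - r


def _sd_capped_cylinder_z(p, radius, z0, z1):
    zc, h = 0.5 * (z0 + z1), 0.5 * (z1 - z0)
    dr = np.hypot(p[..., 0], p[..., 1]) - radius
    dz = np.abs(p[..., 2] - zc) - h
    inside = np.minimum(np.maximum(dr, dz), 0.0)
    outside = np.hypot(np.maximum(dr, 0.0), np.maximum(dz, 0.0))
    return inside + outside


def _sd_round_cone(p, a, b, r1, r2):
    """Sphere-swept cone between sphere (a, r1) and sphere (b, r2)."""
    ba = b - a
    l2 = float(np.dot(ba, ba))
    rr = r1 - r2
    a2 = l2 - rr * rr
    il2 = 1.0 / l2
    pa = p - a
    y = pa @ ba
    z = y - l2
    helper = pa * l2 - np.multiply.outer(y, ba)
    x2 = np.einsum("...i,...i->...", helper, helper)
    y2 = y * y * l2
    z2 = z * z * l2
    k = np.sign(rr) * rr * rr * x2
    d_far = np.sqrt(x2 + z2) * il2 - r2
    d_near = np.sqrt(x2 + y2) * il2 - r1
    d_side = (np.sqrt(x2 * a2 * il2) + y * rr) * il2 - r1
    out = d_side
    out = np.where(np.sign(z) * a2 * z2 > k, d_far, out)
    out = np.where(np.sign(y) * a2 * y2 < k, d_near, out)
    return out


def _sd_ellipsoid(p, center, semiaxes):
    # scaled-space approximation; adequate for blended bumps
    q = (p - center) / np.asarray(semiaxes)
    k1 = np.linalg.norm(q, axis=-1)
    return (k1 - 1.0) * np.min(semiaxes)


def _smin(a, b, k):
    h = np.maximum(k - np.abs(a - b), 0.0) / k
    return np.minimum(a, b) - h * h * k * 0.25


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class _Template:
    """Analytic right-femur template: SDF, sector weights, landmarks."""

    def __init__(self, params: FemurPhantomParams):
        self.params = params
        theta = np.deg2rad(180.0 - params.neck_shaft_angle)
        self.junction = np.array([0.0, 0.0, params.shaft_length])
        self.d_neck = np.array([-np.sin(theta), 0.0, np.cos(theta)])
        self.head_center = self.junction + params.neck_length * self.d_neck
        self.d_shaft = np.array([0.0, 0.0, 1.0])  # pointing proximal
        mp = np.array([-1.0, -1.0, 0.0]) / np.sqrt(2.0)  # medial-posterior
        self.mp = mp
        self.lt_center = (self.junction
                          + mp * (params.shaft_radius + params.lt_radial_offset)
                          + np.array([0.0, 0.0, -params.lt_drop]))
        self.gt_center = self.junction + np.asarray(params.gt_offset)
        # in-plane superior direction for neck cross-sections
        sup = self.d_shaft - (self.d_shaft @ self.d_neck) * self.d_neck
        self.neck_superior = sup / np.linalg.norm(sup)

    # ---- shape -----------------------------------------------------------
    def primitive_sdfs(self, p: np.ndarray) -> dict[str, np.ndarray]:
        pr = self.params
        return {
            "head": _sd_sphere(p, self.head_center, pr.head_radius),
            "neck": _sd_round_cone(p, self.junction, self.head_center,
                                   pr.neck_base_radius, pr.neck_radius),
            "shaft": _sd_capped_cylinder_z(p, pr.shaft_radius, 0.0,
                                           pr.shaft_length + 2.0),
            "gt": _sd_ellipsoid(p, self.gt_center, pr.gt_semiaxes),
            "lt": _sd_ellipsoid(p, self.lt_center, pr.lt_semiaxes),
        }

    def sdf(self, p: np.ndarray) -> np.ndarray:
        d = self.primitive_sdfs(p)
        k = self.params.blend
        out = d["head"]
        for name in ("neck", "shaft", "gt", "lt"):
            out = _smin(out, d[name], k)
        return out

    # ---- anatomical sector weights --------------------------------------
    def sector_weights(self, p: np.ndarray) -> dict[str, np.ndarray]:
        d = self.primitive_sdfs(p)
        tau = 4.0
        raw = {n: np.exp(-np.clip(d[n], -60.0, 60.0) / tau) for n in d}
        total = sum(raw.values())
        return {n: raw[n] / total for n in raw}

    def neck_superior_coord(self, p: np.ndarray) -> np.ndarray:
        rel = p - self.junction
        along = rel @ self.d_neck
        perp = rel - np.multiply.outer(along, self.d_neck)
        return perp @ self.neck_superior

    def cortical_thickness(self, p: np.ndarray) -> np.ndarray:
        t = self.params.cortical_thickness_map
        w = self.sector_weights(p)
        sup = _sigmoid(self.neck_superior_coord(p) / 3.0)
        t_neck = t["neck_inferior"] + (t["neck_superior"] - t["neck_inferior"]) * sup
        w_troch = w["gt"] + w["lt"]
        return (w["head"] * t["head"] + w["neck"] * t_neck
                + w["shaft"] * t["shaft"] + w_troch * t["trochanter"])

    def shell_weight(self, p: np.ndarray) -> np.ndarray:
        """Smooth indicator of the cortical compartment (1 in shell)."""
        d = self.sdf(p)
        t = self.cortical_thickness(p)
        return _sigmoid((d + t) / 0.8) * (d < 0.0)

    def surface_point(self, origin: np.ndarray, direction: np.ndarray,
                      t_max: float = 80.0) -> np.ndarray:
        """Ray-march the SDF from ``origin`` to its zero crossing."""
        direction = direction / np.linalg.norm(direction)
        ts = np.linspace(0.0, t_max, 400)
        pts = origin + np.outer(ts, direction)
        vals = self.sdf(pts)
        idx = np.nonzero(vals > 0)[0]
        if len(idx) == 0 or idx[0] == 0:
            raise ValueError("no surface crossing along ray")
        i = idx[0]
        t0, t1 = ts[i - 1], ts[i]
        v0, v1 = vals[i - 1], vals[i]
        t_hit = t0 + (t1 - t0) * (-v0) / (v1 - v0)
        return origin + t_hit * direction


def make_effect_maps(
    params: FemurPhantomParams,
    q_base: float = -1.2,
    q_superior_neck: float = -3.5,
    q_inferior_neck: float = 0.1,
    s_base: float = 0.4,
    s_medial_shaft_endocortex: float = 2.6,
    b_trabecular: float = 320.0,
    b_cortical_boost: float = 480.0,
    residual_sd: float = 30.0,
) -> EffectMaps:
    """Smooth default effect fields with the expected aging pattern.

    Age slope ``q`` is strongly negative in the superior neck and near
    zero in the inferior neck; BMI slope ``s`` peaks in the medial shaft
    endocortical layer; the intercept ``b`` is elevated in the cortical
    shell. All transitions are smooth in space.
    """
    tmpl = _Template(params)

    def q_field(p):
        p = np.atleast_2d(p)
        w = tmpl.sector_weights(p)
        sup = _sigmoid(tmpl.neck_superior_coord(p) / 3.0)
        q_neck = q_inferior_neck + (q_superior_neck - q_inferior_neck) * sup
        return q_base + w["neck"] * (q_neck - q_base)

    def s_field(p):
        p = np.atleast_2d(p)
        w = tmpl.sector_weights(p)
        medial = _sigmoid(-p[:, 0] / 4.0)
        shell = tmpl.shell_weight(p)
        return s_base + (s_medial_shaft_endocortex - s_base) * (
            w["shaft"] * medial * shell)

    def b_field(p):
        p = np.atleast_2d(p)
        return b_trabecular + b_cortical_boost * tmpl.shell_weight(p)

    return EffectMaps(
        q_field=q_field, s_field=s_field, b_field=b_field,
        residual_sd=residual_sd,
        description={
            "q_base": q_base, "q_superior_neck": q_superior_neck,
            "q_inferior_neck": q_inferior_neck, "s_base": s_base,
            "s_medial_shaft_endocortex": s_medial_shaft_endocortex,
            "b_trabecular": b_trabecular, "b_cortical_boost": b_cortical_boost,
            "residual_sd": residual_sd,
        },
    )


# --------------------------------------------------------------------------
# voxelization

@dataclass
class FemurGeometry:
    """Cached template voxelization shared between subjects."""

    params: FemurPhantomParams
    volume_grid: Volume          # SDF values on the grid
    mask: np.ndarray             # sdf < 0 at voxel centers
    thickness: np.ndarray        # cortical thickness field on the grid
    outer_mesh: trimesh.Trimesh
    inner_mesh: trimesh.Trimesh
    template: _Template
    warnings: list
    field_cache: dict = field(default_factory=dict)

    @property
    def points(self) -> np.ndarray:
        ax = self.volume_grid.axes_world()
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)


def _mesh_from_level_set(values: np.ndarray, spacing, origin,
                         level: float = 0.0) -> trimesh.Trimesh:
    verts, faces, _, _ = marching_cubes(values, level=level,
                                        spacing=tuple(spacing))
    verts = verts + np.asarray(origin)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def build_geometry(params: FemurPhantomParams) -> FemurGeometry:
    """Voxelize the right-side template once; reusable across subjects."""
    tmpl = _Template(params)
    pr = params
    m = pr.margin
    lo = np.array([
        tmpl.head_center[0] - pr.head_radius - m,
        -max(pr.shaft_radius, pr.lt_semiaxes[1] + pr.shaft_radius) - m,
        -m,
    ])
    hi = np.array([
        tmpl.gt_center[0] + pr.gt_semiaxes[0] + m,
        max(pr.shaft_radius, pr.head_radius) + m,
        max(tmpl.head_center[2] + pr.head_radius,
            tmpl.gt_center[2] + pr.gt_semiaxes[2]) + m,
    ])
    spacing = np.asarray(pr.voxel_spacing, dtype=float)
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    origin = lo
    axes = [origin[d] + spacing[d] * np.arange(shape[d]) for d in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    sdf = tmpl.sdf(pts).reshape(shape)
    thickness = tmpl.cortical_thickness(pts).reshape(shape)
    mask = sdf < 0.0
    warnings = []
    min_thick = float(thickness[mask].min()) if mask.any() else 0.0
    if min_thick < float(spacing.max()):
        warnings.append(
            f"cortical shell thinner than one voxel in places "
            f"(min {min_thick:.2f} mm vs spacing {spacing.max():.2f} mm)")
    outer = _mesh_from_level_set(sdf, spacing, origin, 0.0)
    inner = _mesh_from_level_set(sdf + thickness, spacing, origin, 0.0)
    grid = Volume(sdf, spacing, origin)
    return FemurGeometry(params=params, volume_grid=grid, mask=mask,
                         thickness=thickness, outer_mesh=outer,
                         inner_mesh=inner, template=tmpl, warnings=warnings)


def _mirror_mesh(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    verts = mesh.vertices.copy()
    verts[:, 0] = -verts[:, 0]
    out = trimesh.Trimesh(vertices=verts, faces=mesh.faces[:, ::-1].copy(),
                          process=False)
    return out


def _mirror_vec(v: np.ndarray) -> np.ndarray:
    out = np.asarray(v, dtype=float).copy()
    out[0] = -out[0]
    return out


def build_femur(
    params: FemurPhantomParams,
    subject: SubjectRecord,
    maps: EffectMaps,
    seed: int = 0,
    geometry: FemurGeometry | None = None,
) -> tuple[Volume, Volume, GroundTruth]:
    """Voxelize one case: HU volume, femur mask, and ground truth.

    The density and noise are realized in the right-side template frame;
    a left-side subject receives the exact sagittal mirror of the whole
    stack (volume, mask, meshes, landmarks), so left/right pairs are
    bit-identical mirrors by construction.
    """
    geo = geometry if geometry is not None else build_geometry(params)
    tmpl = geo.template
    key = id(maps)
    if key not in geo.field_cache:
        pts = geo.points
        geo.field_cache[key] = tuple(
            f(pts).reshape(geo.mask.shape)
            for f in (maps.q_field, maps.s_field, maps.b_field))
    q_arr, s_arr, b_arr = geo.field_cache[key]
    bmd = subject.age * q_arr + subject.bmi * s_arr + b_arr
    hu = np.where(geo.mask,
                  params.hu_slope * bmd + params.hu_intercept,
                  params.hu_slope * params.soft_tissue_bmd + params.hu_intercept)
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        hu = hu + rng.normal(0.0, params.noise_sd, size=hu.shape)
    grid = geo.volume_grid
    hu_vol = Volume(hu.astype(np.float64), grid.spacing.copy(),
                    grid.origin.copy())
    mask_vol = Volume(geo.mask.astype(np.uint8), grid.spacing.copy(),
                      grid.origin.copy())
    lt_tip = tmpl.surface_point(tmpl.lt_center, tmpl.mp)
    truth = GroundTruth(
        outer_mesh=geo.outer_mesh.copy(),
        inner_mesh=geo.inner_mesh.copy(),
        head_center=tmpl.head_center.copy(),
        head_radius=params.head_radius,
        neck_axis=Axis(tmpl.head_center, -tmpl.d_neck),
        shaft_axis=Axis(tmpl.junction, np.array([0.0, 0.0, -1.0])),
        lesser_trochanter=lt_tip,
        effect_maps=maps,
        side=subject.side,
        warnings=list(geo.warnings),
    )
    if subject.side == "left":
        hu_vol = hu_vol.mirrored_sagittal()
        mask_vol = mask_vol.mirrored_sagittal()
        truth = GroundTruth(
            outer_mesh=_mirror_mesh(truth.outer_mesh),
            inner_mesh=_mirror_mesh(truth.inner_mesh),
            head_center=_mirror_vec(truth.head_center),
            head_radius=truth.head_radius,
            neck_axis=Axis(_mirror_vec(truth.neck_axis.point),
                           _mirror_vec(truth.neck_axis.direction)),
            shaft_axis=Axis(_mirror_vec(truth.shaft_axis.point),
                            _mirror_vec(truth.shaft_axis.direction)),
            lesser_trochanter=_mirror_vec(truth.lesser_trochanter),
            effect_maps=maps,
            side="left",
            warnings=list(truth.warnings),
        )
    return hu_vol, mask_vol, truth


# --------------------------------------------------------------------------
# calibration phantom slab

@dataclass(frozen=True)
class ChamberLayout:
    """Geometry of the six-chamber density calibration rod in-slice.

    Chambers are a horizontal row of cylinders (circular in every axial
    slice), embedded in a resin body; left-to-right order corresponds to
    increasing nominal concentration.
    """

    n_chambers: int = 6
    chamber_radius_mm: float = 9.0
    pitch_mm: float = 24.0
    body_hu: float = -80.0
    background_hu: float = -1000.0
    body_margin_mm: float = 8.0
    detection_threshold_hu: float | None = None

    def centers_mm(self, origin_xy: tuple[float, float]) -> np.ndarray:
        x0, y0 = origin_xy
        return np.array([[x0 + i * self.pitch_mm, y0]
                         for i in range(self.n_chambers)])


DEFAULT_CONCENTRATIONS = (0.0, 100.0, 200.0, 400.0, 600.0, 800.0)


def build_phantom_slab(
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS,
    params: FemurPhantomParams = FemurPhantomParams(),
    layout: ChamberLayout = ChamberLayout(),
    n_slices: int = 12,
    seed: int = 0,
    intercept_drift: Callable[[int], float] | None = None,
    spacing_xy: float = 1.0,
) -> Volume:
    """Voxelize a slab of the calibration rod alone.

    Chamber interiors carry ``hu_slope * c + hu_intercept`` (plus the
    optional per-slice ``intercept_drift(k)`` and Gaussian noise); the
    surrounding body is resin-like, the rest air. Chamber centers are
    identical in every slice.
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any(np.diff(conc) < 0):
        raise ValueError("concentrations must be sorted ascending")
    lay = layout
    if lay.pitch_mm <= 2 * lay.chamber_radius_mm:
        raise ValueError("chamber layout overlaps: pitch <= diameter")
    r = lay.chamber_radius_mm
    pad = r + lay.body_margin_mm
    centers = lay.centers_mm((pad + 4.0, pad + 4.0))
    nx = int(np.ceil((centers[-1, 0] + pad + 4.0) / spacing_xy)) + 1
    ny = int(np.ceil((centers[0, 1] + pad + 4.0) / spacing_xy)) + 1
    spacing = np.array([spacing_xy, spacing_xy, 1.0])
    origin = np.zeros(3)
    xs = origin[0] + spacing[0] * np.arange(nx)
    ys = origin[1] + spacing[1] * np.arange(ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    body = ((X >= centers[0, 0] - pad) & (X <= centers[-1, 0] + pad)
            & (Y >= centers[0, 1] - pad) & (Y <= centers[0, 1] + pad))
    data = np.empty((nx, ny, n_slices), dtype=float)
    rng = np.random.default_rng(seed)
    for k in range(n_slices):
        drift = float(intercept_drift(k)) if intercept_drift is not None else 0.0
        sl = np.where(body, lay.body_hu, lay.background_hu).astype(float)
        for c, (cx, cy) in zip(conc, centers):
            inside = (X - cx) ** 2 + (Y - cy) ** 2 <= r ** 2
            sl[inside] = params.hu_slope * c + params.hu_intercept + drift
        if params.noise_sd > 0:
            sl = sl + rng.normal(0.0, params.noise_sd, size=sl.shape)
        data[:, :, k] = sl
    return Volume(data, spacing, origin)


def embed_phantom(
    hu_volume: Volume,
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS,
    params: FemurPhantomParams = FemurPhantomParams(),
    layout: ChamberLayout = ChamberLayout(),
    seed: int = 0,
    intercept_drift: Callable[[int], float] | None = None,
) -> Volume:
    """Stamp the calibration rod into every axial slice of a case volume.

    The rod is appended on the posterior (-y) side of the grid, mimicking
    a phantom built into the scanner table; the femur voxels are
    untouched. Returns an enlarged copy.
    """
    conc = np.asarray(concentrations, dtype=float)
    lay = layout
    r = lay.chamber_radius_mm
    pad = r + lay.body_margin_mm
    sp = hu_volume.spacing
    extra_mm = 2 * pad + 6.0
    n_extra = int(np.ceil(extra_mm / sp[1])) + 1
    nx, ny, nz = hu_volume.shape
    data = np.full((nx, ny + n_extra, nz),
                   lay.background_hu, dtype=float)
    data[:, n_extra:, :] = hu_volume.data
    origin = hu_volume.origin.copy()
    origin[1] -= n_extra * sp[1]
    xs = origin[0] + sp[0] * np.arange(nx)
    ys = origin[1] + sp[1] * np.arange(ny + n_extra)
    X, Y = np.meshgrid(xs, ys[:n_extra], indexing="ij")
    row_y = origin[1] + pad
    total_w = (lay.n_chambers - 1) * lay.pitch_mm
    x_start = xs.mean() - total_w / 2.0
    centers = np.array([[x_start + i * lay.pitch_mm, row_y]
                        for i in range(lay.n_chambers)])
    body = ((X >= centers[0, 0] - pad) & (X <= centers[-1, 0] + pad)
            & (Y >= row_y - pad) & (Y <= row_y + pad))
    rng = np.random.default_rng(seed)
    for k in range(nz):
        drift = float(intercept_drift(k)) if intercept_drift is not None else 0.0
        sl = data[:, :n_extra, k]
        sl[body] = lay.body_hu
        for c, (cx, cy) in zip(conc, centers):
            inside = (X - cx) ** 2 + (Y - cy) ** 2 <= r ** 2
            sl[inside] = params.hu_slope * c + params.hu_intercept + drift
        if params.noise_sd > 0:
            sl += rng.normal(0.0, params.noise_sd, size=sl.shape)
        data[:, :n_extra, k] = sl
    return Volume(data, sp.copy(), origin)
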