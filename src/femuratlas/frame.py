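"""Personalized proximal-femur coordinate frame from the periosteal mesh.

The frame consists of two intersecting axes (one through the femoral
neck, one through the shaft), the femoral head center and radius, the
lesser-trochanter landmark, a cutting plane orthogonal to the neck axis
separating the neck-governed from the shaft-governed region, and a
distal crop level scaled by the femur volume above the lesser
trochanter.

All estimators operate on mesh geometry alone (no world-axis
assumptions), so the frame is equivariant under rigid transforms of the
input. Estimation can be bypassed entirely by supplying ground-truth
frame elements, which keeps downstream modules testable in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .core import Axis, Plane, Volume, dump_json, load_json

__all__ = [
    "FemurFrame",
    "UnreliableFitError",
    "fit_head_sphere",
    "estimate_shaft_axis",
    "estimate_neck_axis",
    "refine_axes",
    "place_cutting_plane",
    "detect_lesser_trochanter",
    "crop_distal",
    "mirror_left",
    "estimate_frame",
    "volume_above_lt",
]

AXIS_INTERSECT_TOL_MM = 2.0
AREA_INCREASE_THRESHOLD = 0.15   # forward relative area growth per station
CUTTING_PLANE_STEP_MM = 3.0
CROP_SCALE_DEFAULT = 0.9         # crop offset = c * V_aboveLT^(1/3)


class UnreliableFitError(RuntimeError):
    pass


@dataclass
class FemurFrame:
    head_center: np.ndarray
    head_radius: float
    neck_axis: Axis              # direction points from head toward shaft
    shaft_axis: Axis             # direction points distal
    lesser_trochanter: np.ndarray
    cutting_plane: Plane
    crop_level: float            # coordinate along shaft_axis direction
    flags: list = field(default_factory=list)

    def __post_init__(self):
        self.head_center = np.asarray(self.head_center, dtype=float)
        self.lesser_trochanter = np.asarray(self.lesser_trochanter, dtype=float)
        gap = _closest_approach(self.neck_axis, self.shaft_axis)[2]
        if gap > AXIS_INTERSECT_TOL_MM:
            raise ValueError(
                f"neck and shaft axes do not intersect (gap {gap:.2f} mm)")
        if abs(self.cutting_plane.normal @ self.neck_axis.direction) < 0.999:
            raise ValueError("cutting plane normal not parallel to neck axis")

    def to_json(self, path) -> None:
        dump_json({
            "head_center": self.head_center,
            "head_radius": self.head_radius,
            "neck_axis": {"point": self.neck_axis.point,
                          "direction": self.neck_axis.direction},
            "shaft_axis": {"point": self.shaft_axis.point,
                           "direction": self.shaft_axis.direction},
            "lesser_trochanter": self.lesser_trochanter,
            "cutting_plane": {"point": self.cutting_plane.point,
                              "normal": self.cutting_plane.normal},
            "crop_level": self.crop_level,
            "flags": self.flags,
        }, path)

    @classmethod
    def from_json(cls, path) -> "FemurFrame":
        d = load_json(path)
        return cls(
            head_center=np.array(d["head_center"]),
            head_radius=float(d["head_radius"]),
            neck_axis=Axis(d["neck_axis"]["point"], d["neck_axis"]["direction"]),
            shaft_axis=Axis(d["shaft_axis"]["point"], d["shaft_axis"]["direction"]),
            lesser_trochanter=np.array(d["lesser_trochanter"]),
            cutting_plane=Plane(d["cutting_plane"]["point"],
                                d["cutting_plane"]["normal"]),
            crop_level=float(d["crop_level"]),
            flags=list(d.get("flags", [])),
        )


# --------------------------------------------------------------------------
# helpers

def _closest_approach(a: Axis, b: Axis):
    """Closest points between two lines and their separation."""
    d1, d2 = a.direction, b.direction
    r = a.point - b.point
    a11, a12, a22 = d1 @ d1, d1 @ d2, d2 @ d2
    b1, b2 = d1 @ r, d2 @ r
    det = a11 * a22 - a12 * a12
    if det < 1e-12:  # parallel
        t1, t2 = 0.0, b2 / a22
    else:
        t1 = (a12 * b2 - a22 * b1) / det
        t2 = (a11 * b2 - a12 * b1) / det
    p1, p2 = a.at(t1), b.at(t2)
    return p1, p2, float(np.linalg.norm(p1 - p2))


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = np.asarray(normal, dtype=float)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(n @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2


def _cross_sections(mesh: trimesh.Trimesh, origin, normal, near_point=None):
    """Planar cross-section components: list of (area, centroid_3d).

    Each closed intersection loop is one component; area and centroid
    come from the shoelace formula in an in-plane basis.
    """
    origin = np.asarray(origin, dtype=float)
    sec = mesh.section(plane_origin=origin, plane_normal=normal)
    if sec is None:
        return []
    e1, e2 = _plane_basis(normal)
    out = []
    for loop in sec.discrete:
        rel = loop - origin
        x, y = rel @ e1, rel @ e2
        # shoelace; loop is closed (first point repeated last)
        cross = x[:-1] * y[1:] - x[1:] * y[:-1]
        area = 0.5 * cross.sum()
        if abs(area) < 1e-9:
            continue
        cx = np.sum((x[:-1] + x[1:]) * cross) / (6.0 * area)
        cy = np.sum((y[:-1] + y[1:]) * cross) / (6.0 * area)
        c3 = origin + cx * e1 + cy * e2
        out.append((abs(float(area)), c3))
    return out


def _section_near(sections, point):
    """Pick the component whose centroid is nearest ``point``."""
    if not sections:
        return None
    point = np.asarray(point, dtype=float)
    return min(sections, key=lambda s: np.linalg.norm(s[1] - point))


def _fit_sphere_lsq(points: np.ndarray):
    """Algebraic least-squares sphere (Coope's linearization)."""
    p = np.asarray(points, dtype=float)
    A = np.hstack([2.0 * p, np.ones((len(p), 1))])
    b = (p ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise UnreliableFitError("degenerate sphere fit (non-positive radius)")
    return center, float(np.sqrt(r2))


def _pca_axis(points: np.ndarray) -> np.ndarray:
    p = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(p, full_matrices=False)
    return vt[0]


# --------------------------------------------------------------------------
# operations

def fit_head_sphere(
    outer_mesh: trimesh.Trimesh,
    seed_point: np.ndarray | None = None,
    max_residual_fraction: float = 0.15,
) -> tuple[np.ndarray, float, float]:
    """Least-squares sphere over the femoral-head vertices.

    The head patch is found geometrically: the vertex farthest from the
    rough long axis of the mesh seeds a local patch (the head protrudes
    farther off-axis than the greater trochanter); iterated band
    reselection around the current sphere then grows the patch over the
    whole articular surface while shedding neck vertices.

    Returns (center, radius, residual RMS). A residual RMS above
    ``max_residual_fraction * radius`` raises :class:`UnreliableFitError`.
    """
    verts = np.asarray(outer_mesh.vertices, dtype=float)
    if len(verts) < 10:
        raise UnreliableFitError("too few vertices for a sphere fit")
    if seed_point is None:
        # The head apex protrudes farther off the shaft axis than any
        # other structure; fall back to the rough PCA axis for partial
        # meshes where no shaft is identifiable.
        try:
            axis = estimate_shaft_axis(outer_mesh)
        except UnreliableFitError:
            axis = Axis(verts.mean(axis=0), _pca_axis(verts))
        dists = axis.distance(verts)
        seed_point = verts[int(np.argmax(dists))]
    seed_point = np.asarray(seed_point, dtype=float)
    # initial patch: vertices near the seed, sized by the mesh scale
    scale = float(np.linalg.norm(verts.max(axis=0) - verts.min(axis=0)))
    patch_r = 0.18 * scale
    patch = verts[np.linalg.norm(verts - seed_point, axis=1) < patch_r]
    if len(patch) < 10:
        raise UnreliableFitError("head seed patch too small")
    center, radius = _fit_sphere_lsq(patch)
    for _ in range(15):
        d = np.linalg.norm(verts - center, axis=1)
        band = np.abs(d - radius) < 0.12 * radius
        if band.sum() < 10:
            break
        new_center, new_radius = _fit_sphere_lsq(verts[band])
        if (np.linalg.norm(new_center - center) < 1e-9
                and abs(new_radius - radius) < 1e-9):
            center, radius = new_center, new_radius
            break
        center, radius = new_center, new_radius
    d = np.linalg.norm(verts - center, axis=1)
    band = np.abs(d - radius) < 0.12 * radius
    if band.sum() < 10:
        raise UnreliableFitError("no spherical region found")
    rms = float(np.sqrt(np.mean((d[band] - radius) ** 2)))
    if rms > max_residual_fraction * radius:
        raise UnreliableFitError(
            f"sphere fit residual RMS {rms:.2f} mm exceeds "
            f"{max_residual_fraction:.0%} of radius {radius:.2f} mm")
    return center, radius, rms


def estimate_shaft_axis(
    outer_mesh: trimesh.Trimesh,
    distal_band: tuple[float, float] = (0.05, 0.45),
    n_stations: int = 10,
) -> Axis:
    """Line through centroids of distal shaft cross-sections.

    The rough long axis comes from vertex PCA; the distal end is the one
    with the smaller maximal off-axis extent (the proximal end carries
    head and trochanters). Cross-sections are taken in the fractional
    band ``distal_band`` of the length from the distal end, their
    centroids fitted with a total-least-squares line oriented distally.
    """
    verts = np.asarray(outer_mesh.vertices, dtype=float)
    u = _pca_axis(verts)
    centroid = verts.mean(axis=0)
    t = (verts - centroid) @ u
    lo, hi = t.min(), t.max()
    rough = Axis(centroid, u)
    r = rough.distance(verts)
    # which end is distal? compare off-axis extent in the two end thirds
    third = (hi - lo) / 3.0
    r_low = r[t < lo + third].max()
    r_high = r[t > hi - third].max()
    if r_low > r_high:          # proximal end sits at low t: flip
        u = -u
        t = -t
        lo, hi = t.min(), t.max()
    length = hi - lo
    stations = lo + length * np.linspace(distal_band[0], distal_band[1],
                                         n_stations)
    cents = []
    for s in stations:
        secs = _cross_sections(outer_mesh, centroid + s * u, u)
        pick = _section_near(secs, centroid + s * u)
        if pick is not None:
            cents.append(pick[1])
    if len(cents) < 3:
        raise UnreliableFitError(
            f"only {len(cents)} usable distal cross-sections")
    cents = np.asarray(cents)
    mean = cents.mean(axis=0)
    d = _pca_axis(cents)
    if d @ u > 0:               # u points proximal after flip handling above
        d = -d
    # direction convention: pointing distal
    return Axis(mean, d)


def estimate_neck_axis(
    outer_mesh: trimesh.Trimesh,
    head_center: np.ndarray,
    head_radius: float | None = None,
    shaft_axis: Axis | None = None,
    band: tuple[float, float] = (1.1, 1.6),
    n_stations: int = 8,
    n_iter: int = 8,
) -> Axis:
    """Neck line through the head center.

    Cross-sections orthogonal to the current direction are taken in a
    band of distances from the head center (in units of head radius,
    i.e. just lateral of the articular surface up to the trochanteric
    base); the direction is refit as the principal direction of the
    centroids relative to the head center and iterated.

    Returned direction points from the head toward the shaft.
    """
    head_center = np.asarray(head_center, dtype=float)
    verts = np.asarray(outer_mesh.vertices, dtype=float)
    if head_radius is None:
        head_radius = float(np.percentile(
            np.linalg.norm(verts - head_center, axis=1), 5))
    if shaft_axis is not None:
        foot = shaft_axis.at(shaft_axis.project(head_center))
        d = head_center - foot
        n = np.linalg.norm(d)
        if n < 1e-6:
            raise UnreliableFitError("head center lies on the shaft axis")
        d0 = -d / n
    else:
        d0 = -(head_center - verts.mean(axis=0))
        n = np.linalg.norm(d0)
        if n < 1e-6:
            raise UnreliableFitError("cannot seed a neck direction")
        d0 = d0 / n
    d = d0
    last_cents = None
    for _ in range(n_iter):
        stations = head_radius * np.linspace(band[0], band[1], n_stations)
        cents = []
        for s in stations:
            origin = head_center + s * d
            secs = _cross_sections(outer_mesh, origin, d)
            pick = _section_near(secs, origin)
            if pick is not None:
                cents.append(pick[1])
        if len(cents) < 3:
            raise UnreliableFitError("no identifiable neck band")
        cents = np.asarray(cents)
        rel = cents - head_center
        new_d = _pca_axis(rel)
        if new_d @ d < 0:
            new_d = -new_d
        d = new_d
        last_cents = cents
    return Axis(head_center, d)


def refine_axes(neck_axis: Axis, shaft_axis: Axis) -> tuple[Axis, Axis]:
    """Snap both axes to their common closest-approach midpoint.

    The neck axis keeps passing through its anchor point (the head
    center); its direction is re-aimed at the midpoint. The shaft axis
    keeps its direction and is shifted to pass through the midpoint.
    """
    p1, p2, _ = _closest_approach(neck_axis, shaft_axis)
    mid = 0.5 * (p1 + p2)
    new_neck_dir = mid - neck_axis.point
    n = np.linalg.norm(new_neck_dir)
    if n < 1e-9:
        return neck_axis, Axis(mid, shaft_axis.direction)
    if new_neck_dir @ neck_axis.direction < 0:
        new_neck_dir = -new_neck_dir
    return (Axis(neck_axis.point, new_neck_dir),
            Axis(mid, shaft_axis.direction))


def place_cutting_plane(
    outer_mesh: trimesh.Trimesh,
    neck_axis: Axis,
    threshold: float = AREA_INCREASE_THRESHOLD,
    step_mm: float = CUTTING_PLANE_STEP_MM,
    max_extent_mm: float = 120.0,
) -> tuple[Plane, bool]:
    """Plane orthogonal to the neck axis before the trochanteric flare.

    Cross-section areas are profiled lateral-ward from the head center
    along the neck axis; the plane lands at the most lateral station
    whose forward relative area growth stays below ``threshold``. A flat
    profile (no flare found) falls back to the most lateral station and
    raises the fallback flag.
    """
    stations = np.arange(0.0, max_extent_mm + step_mm, step_mm)
    areas = []
    kept_stations = []
    for s in stations:
        origin = neck_axis.at(s)
        secs = _cross_sections(outer_mesh, origin, neck_axis.direction)
        pick = _section_near(secs, origin)
        if pick is None:
            break
        areas.append(pick[0])
        kept_stations.append(s)
    if len(areas) < 3:
        raise UnreliableFitError("too few stations for an area profile")
    areas = np.asarray(areas)
    growth = np.diff(areas) / areas[:-1]
    jump = np.nonzero(growth > threshold)[0]
    if len(jump) == 0:
        plane = Plane(neck_axis.at(kept_stations[-1]), neck_axis.direction)
        return plane, True
    j = int(jump[0])
    return Plane(neck_axis.at(kept_stations[j]), neck_axis.direction), False


def detect_lesser_trochanter(
    outer_mesh: trimesh.Trimesh,
    shaft_axis: Axis,
    neck_axis: Axis,
    head_center: np.ndarray,
    side: str = "right",
) -> np.ndarray:
    """Landmark at the maximal medial-posterior protrusion off the shaft.

    Medial is the in-plane direction from the shaft axis toward the head
    center; posterior follows from the side-dependent handedness
    (anterior = medial x distal for a right femur). The landmark is the
    vertex maximizing radial distance from the shaft axis among vertices
    whose off-axis direction lies in the medial-posterior quadrant,
    below the intertrochanteric region.
    """
    verts = np.asarray(outer_mesh.vertices, dtype=float)
    dist_dir = shaft_axis.direction          # points distal
    medial = head_center - shaft_axis.at(shaft_axis.project(head_center))
    medial = medial - (medial @ dist_dir) * dist_dir
    medial /= np.linalg.norm(medial)
    anterior = np.cross(dist_dir, medial)    # right-femur handedness
    if side == "left":
        anterior = -anterior
    elif side != "right":
        raise ValueError(f"unknown side {side!r}")
    mp = (medial - anterior) / np.sqrt(2.0)   # medial-posterior bisector
    t = shaft_axis.project(verts)
    # search distal of the axis intersection (below the neck base) but
    # within the proximal half of the shaft
    p1, p2, _ = _closest_approach(neck_axis, shaft_axis)
    t_junction = shaft_axis.project(0.5 * (p1 + p2))
    t_hi = t.max()
    sel = (t > t_junction + 0.05 * (t_hi - t_junction)) & \
          (t < t_junction + 0.55 * (t_hi - t_junction))
    rel = verts - shaft_axis.point
    along = rel @ dist_dir
    perp = rel - np.outer(along, dist_dir)
    r = np.linalg.norm(perp, axis=1)
    with np.errstate(invalid="ignore"):
        cosang = (perp @ mp) / np.where(r > 0, r, 1.0)
    cand = sel & (cosang > np.cos(np.deg2rad(50.0)))
    if not cand.any():
        raise UnreliableFitError("no medial-posterior protrusion found")
    score = np.where(cand, perp @ mp, -np.inf)
    return verts[int(np.argmax(score))]


def volume_above_lt(mask: Volume, shaft_axis: Axis,
                    lesser_trochanter: np.ndarray) -> float:
    """Femur mask volume proximal of the lesser-trochanter level, mm^3."""
    idx = np.argwhere(np.asarray(mask.data) > 0)
    if len(idx) == 0:
        raise ValueError("empty femur mask")
    pts = mask.index_to_world(idx)
    t = shaft_axis.project(pts)
    t_lt = shaft_axis.project(np.asarray(lesser_trochanter, dtype=float))
    return float(np.count_nonzero(t <= t_lt) * mask.voxel_volume)


def crop_distal(
    outer_mesh: trimesh.Trimesh,
    shaft_axis: Axis,
    lesser_trochanter: np.ndarray,
    volume_above: float,
    scale: float = CROP_SCALE_DEFAULT,
) -> tuple[float, bool]:
    """Distal crop coordinate along the shaft axis, size-scaled.

    crop = LT level + scale * V^(1/3), with V the femur volume above the
    lesser trochanter; the cube root makes the offset scale linearly
    with femur size. Clamped (and flagged) at the available mesh extent.
    """
    if volume_above <= 0:
        raise ValueError("volume above lesser trochanter must be positive")
    t_lt = shaft_axis.project(np.asarray(lesser_trochanter, dtype=float))
    crop = t_lt + scale * volume_above ** (1.0 / 3.0)
    t_max = shaft_axis.project(np.asarray(outer_mesh.vertices)).max()
    if crop > t_max:
        return float(t_max), True
    return float(crop), False


def mirror_left(obj, side: str = "left"):
    """Sagittal reflection (across world x=0) of a mesh or volume.

    Triangle winding is flipped so normals stay outward; applying the
    operation twice is the identity. The side must be known.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    if isinstance(obj, Volume):
        return obj.mirrored_sagittal()
    if isinstance(obj, trimesh.Trimesh):
        verts = obj.vertices.copy()
        verts[:, 0] = -verts[:, 0]
        return trimesh.Trimesh(vertices=verts, faces=obj.faces[:, ::-1].copy(),
                               process=False)
    raise TypeError(f"cannot mirror object of type {type(obj)!r}")


def estimate_frame(
    outer_mesh: trimesh.Trimesh,
    mask: Volume | None = None,
    side: str = "right",
    area_threshold: float = AREA_INCREASE_THRESHOLD,
    crop_scale: float = CROP_SCALE_DEFAULT,
) -> FemurFrame:
    """Full frame estimation chain on one (right-oriented) femur mesh.

    Left femurs must be mirrored to right-side geometry first; pass the
    original side only for bookkeeping. When a mask is given the crop
    scaling uses the true voxel volume above the lesser trochanter,
    otherwise the mesh volume above that level.
    """
    head_center, head_radius, _ = fit_head_sphere(outer_mesh)
    shaft = estimate_shaft_axis(outer_mesh)
    neck = estimate_neck_axis(outer_mesh, head_center, head_radius, shaft)
    neck, shaft = refine_axes(neck, shaft)
    plane, plane_flag = place_cutting_plane(outer_mesh, neck,
                                            threshold=area_threshold)
    lt = detect_lesser_trochanter(outer_mesh, shaft, neck, head_center,
                                  side="right")
    if mask is not None:
        v_above = volume_above_lt(mask, shaft, lt)
    else:
        t = shaft.project(np.asarray(outer_mesh.vertices))
        t_lt = shaft.project(lt)
        frac = np.clip((t_lt - t.min()) / (t.max() - t.min()), 0.05, 1.0)
        v_above = float(abs(outer_mesh.volume) * frac)
    crop, crop_flag = crop_distal(outer_mesh, shaft, lt, v_above,
                                  scale=crop_scale)
    flags = []
    if plane_flag:
        flags.append("cutting_plane_fallback")
    if crop_flag:
        flags.append("crop_clamped")
    return FemurFrame(
        head_center=head_center,
        head_radius=head_radius,
        neck_axis=neck,
        shaft_axis=shaft,
        lesser_trochanter=lt,
        cutting_plane=plane,
        crop_level=crop,
        flags=flags,
    )
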