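"""Anatomically corresponding cylindrical point cloud on a femur frame.

The proximal femur is discretized in cylindrical coordinates (r, phi, z):
39 z-stations (0-12 governed by the neck axis, 13-38 by the shaft axis),
12 angular directions per station in 30-degree steps, and per-direction
radial fractions from the axis (r=0) to the surface (r=1). Anchor
stations sit on anatomical landmarks — head surface (z=0), head center
(z=5), cutting plane (z=12), most superior shaft level (z=13), cutting
plane on the superior neck surface (z=15), lesser trochanter (z=28),
distal crop (z=38) — with the remaining stations equidistant between
anchors, so identical (z, phi, radial-ordinal) indices denote homologous
positions across femurs.

Radial point counts are fixed on a reference geometry and reused for
every femur, which is what makes the correspondence exact by
construction; points falling outside a particular femur are only
flagged, never re-spaced.

Angular convention: angles rotate counterclockwise about the governing
axis oriented toward the viewer standing proximal (at the head for neck
stations, above the hip for shaft stations) of a *right* femur; left
femurs are mirrored to right-side geometry before cloud construction,
never re-signed. phi=0 points superior on neck planes and lateral on
shaft planes; phi index 7 (nominally 210 degrees) is re-aimed at the
lesser trochanter, with indices 8-11 equally spaced up to 360 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from .core import Axis, Plane, Volume, dump_json, load_json
from .frame import FemurFrame
from .raycast import TriangleRayCaster

__all__ = [
    "ZStation",
    "CloudConfig",
    "AtlasPointCloud",
    "discretize_axes",
    "generate_directions",
    "cast_ray_to_surface",
    "place_radial_points",
    "build_cloud",
]

N_STATIONS = 39
N_DIRECTIONS = 12
NECK_Z_MAX = 12          # z <= 12 is neck-governed
LT_Z_INDEX = 28
SUPERIOR_NECK_Z_INDEX = 15
LT_PHI_INDEX = 7         # nominal 210 degrees, re-aimed at the LT landmark
RADIAL_SPACING_MM = 4.0  # target spacing on the reference geometry
INTERTROCH_Z_RANGE = (13, 27)   # cutting plane may replace the surface here
_STATION_GUARD_MM = 1.5  # keeps extreme stations off degenerate tangent planes


@dataclass(frozen=True)
class ZStation:
    z_index: int
    region: str            # "neck_side" | "shaft_side"
    axis: Axis             # governing axis (direction away from the head)
    t: float               # coordinate along the governing axis
    origin: np.ndarray
    normal: np.ndarray


@dataclass
class CloudConfig:
    """Reference configuration shared across femurs for correspondence."""

    radial_spacing_mm: float = RADIAL_SPACING_MM
    counts: dict | None = None   # (z_index, phi_index) -> interval count
    reference_id: str | None = None

    def to_dict(self) -> dict:
        return {
            "radial_spacing_mm": self.radial_spacing_mm,
            "reference_id": self.reference_id,
            "counts": (None if self.counts is None else
                       {f"{z},{p}": c for (z, p), c in self.counts.items()}),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CloudConfig":
        counts = d.get("counts")
        if counts is not None:
            counts = {tuple(int(v) for v in k.split(",")): int(c)
                      for k, c in counts.items()}
        return cls(radial_spacing_mm=float(d["radial_spacing_mm"]),
                   counts=counts, reference_id=d.get("reference_id"))


@dataclass
class AtlasPointCloud:
    """Indexed cloud points with world positions and validity flags."""

    points: pd.DataFrame   # z_index, phi_index, radial_ordinal, r, x, y, z,
                           # region, inside_bone, valid
    config: CloudConfig
    frame: FemurFrame | None = None
    removed_points: list = field(default_factory=list)

    def index_set(self) -> set[tuple[int, int, int]]:
        return set(map(tuple, self.points[
            ["z_index", "phi_index", "radial_ordinal"]].to_numpy()))

    @property
    def positions(self) -> np.ndarray:
        return self.points[["x", "y", "z"]].to_numpy()

    def to_csv(self, path, config_path=None) -> None:
        self.points.to_csv(path, index=False)
        if config_path is not None:
            dump_json(self.config.to_dict(), config_path)

    @classmethod
    def from_csv(cls, path, config_path=None) -> "AtlasPointCloud":
        df = pd.read_csv(path)
        cfg = (CloudConfig.from_dict(load_json(config_path))
               if config_path is not None else CloudConfig())
        return cls(points=df, config=cfg)


# --------------------------------------------------------------------------

def _project_onto_plane(v: np.ndarray, normal: np.ndarray) -> np.ndarray:
    return v - (v @ normal) * normal


def discretize_axes(frame: FemurFrame, outer_mesh) -> list[ZStation]:
    """The 39 z-stations with anatomical anchors.

    Neck-side coordinates run along the neck axis from the head-surface
    intersection; shaft-side coordinates run distally along the shaft
    axis from the most superior mesh level to the crop level.
    """
    neck, shaft = frame.neck_axis, frame.shaft_axis
    mesh = outer_mesh.mesh if hasattr(outer_mesh, "mesh") else outer_mesh
    verts = np.asarray(mesh.vertices, dtype=float)

    # --- neck-side anchors (t along neck axis, 0 at head center) ---------
    # head surface pierced on the articular (anti-shaft) side
    d_head = _ray_distance(mesh, neck.point, -neck.direction)
    if d_head is None or not np.isfinite(d_head):
        raise ValueError("neck axis does not pierce the head surface")
    t_head_surface = -d_head
    t_center = 0.0
    t_plane = neck.project(frame.cutting_plane.point)
    if not t_head_surface < t_center < t_plane:
        raise ValueError("neck anchors out of order along the neck axis")

    # --- shaft-side anchors (t along shaft axis, increasing distally) ----
    ts = shaft.project(verts)
    t_top = float(ts.min()) + _STATION_GUARD_MM
    t_sup_neck = _superior_neck_level(mesh, frame)
    t_lt = float(shaft.project(frame.lesser_trochanter))
    t_crop = float(frame.crop_level)
    if t_crop > ts.max():
        t_crop = float(ts.max()) - _STATION_GUARD_MM
    if not t_top < t_sup_neck < t_lt < t_crop:
        raise ValueError(
            "shaft anchors out of order: "
            f"top {t_top:.1f}, superior neck {t_sup_neck:.1f}, "
            f"LT {t_lt:.1f}, crop {t_crop:.1f}")

    t_neck = np.concatenate([
        np.linspace(t_head_surface, t_center, 6),
        np.linspace(t_center, t_plane, 8)[1:],
    ])
    t_shaft = np.concatenate([
        np.linspace(t_top, t_sup_neck, 3),
        np.linspace(t_sup_neck, t_lt, 14)[1:],
        np.linspace(t_lt, t_crop, 11)[1:],
    ])
    stations = []
    for z, t in enumerate(t_neck):
        stations.append(ZStation(z, "neck_side", neck, float(t),
                                 neck.at(float(t)), neck.direction))
    for i, t in enumerate(t_shaft):
        z = 13 + i
        stations.append(ZStation(z, "shaft_side", shaft, float(t),
                                 shaft.at(float(t)), shaft.direction))
    for axis_ts in (t_neck, t_shaft):
        if np.any(np.diff(axis_ts) <= 0):
            raise ValueError("z-stations not strictly monotone along axis")
    return stations


def _as_caster(mesh_or_caster) -> TriangleRayCaster:
    if isinstance(mesh_or_caster, TriangleRayCaster):
        return mesh_or_caster
    return TriangleRayCaster(mesh_or_caster)


def _ray_distance(mesh, origin, direction, tri_index=None):
    """Distance to the farthest mesh intersection along a ray, or None."""
    caster = _as_caster(mesh)
    return caster.farthest_hit(origin, direction, tri_index)


def _superior_neck_level(mesh, frame: FemurFrame) -> float:
    """Shaft-axis level of the cutting plane on the superior neck surface."""
    sec = mesh.section(plane_origin=frame.cutting_plane.point,
                       plane_normal=frame.cutting_plane.normal)
    if sec is None:
        raise ValueError("cutting plane does not intersect the mesh")
    pts = np.vstack(sec.discrete)
    t = frame.shaft_axis.project(pts)
    return float(t.min())     # most proximal = superior


def generate_directions(
    station: ZStation,
    frame: FemurFrame,
    lt_azimuth_deg: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """The 12 in-plane unit directions and their angles for one station.

    Returns (directions (12, 3), angles_deg (12,)). On shaft-side
    stations with a known lesser-trochanter azimuth, index 7 is pinned
    to that azimuth and indices 8-11 re-spaced equally up to 360.
    """
    n = station.normal
    if station.region == "neck_side":
        # superior = proximal shaft direction projected in-plane
        e0 = _project_onto_plane(-frame.shaft_axis.direction, n)
    else:
        # lateral = head-to-shaft neck direction projected in-plane
        e0 = _project_onto_plane(frame.neck_axis.direction, n)
    norm = np.linalg.norm(e0)
    if norm < 1e-9:
        raise ValueError(
            f"degenerate zero-angle projection at z={station.z_index}")
    e0 /= norm
    rot = -n        # proximal-ward rotation axis: counterclockwise convention
    e90 = np.cross(rot, e0)
    angles = np.arange(N_DIRECTIONS) * 30.0
    if (lt_azimuth_deg is not None and station.region == "shaft_side"):
        a = float(lt_azimuth_deg) % 360.0
        if not 90.0 < a < 330.0:
            raise ValueError(f"implausible LT azimuth {a:.1f} degrees")
        angles = angles.astype(float)
        angles[LT_PHI_INDEX] = a
        angles[LT_PHI_INDEX + 1:] = a + (360.0 - a) * np.arange(
            1, N_DIRECTIONS - LT_PHI_INDEX) / (N_DIRECTIONS - LT_PHI_INDEX)
    rad = np.deg2rad(angles)
    dirs = (np.cos(rad)[:, None] * e0[None, :]
            + np.sin(rad)[:, None] * e90[None, :])
    return dirs, angles


def lt_azimuth(frame: FemurFrame, stations: list[ZStation]) -> float:
    """In-plane azimuth of the LT landmark at its own station (z=28)."""
    st = stations[LT_Z_INDEX]
    dirs, _ = generate_directions(st, frame, lt_azimuth_deg=None)
    e0, e90 = dirs[0], np.cross(-st.normal, dirs[0])
    rel = _project_onto_plane(
        np.asarray(frame.lesser_trochanter, dtype=float) - st.origin,
        st.normal)
    ang = np.degrees(np.arctan2(rel @ e90, rel @ e0)) % 360.0
    return float(ang)


def cast_ray_to_surface(
    origin: np.ndarray,
    direction: np.ndarray,
    outer_mesh,
    cutting_plane: Plane | None = None,
    region: str = "neck_side",
    z_index: int = 0,
    tri_index: np.ndarray | None = None,
) -> float | None:
    """Radial extent r=1 along one direction, in mm; None when invalid.

    The farthest surface intersection defines r=1 (greater-trochanter
    stations can produce several crossings). On shaft-side stations in
    the intertrochanteric range the cutting plane substitutes for the
    surface whenever the ray meets the plane before the surface.
    """
    d_surface = _ray_distance(outer_mesh, origin, direction, tri_index)
    if d_surface is None:
        return None
    if (cutting_plane is not None and region == "shaft_side"
            and INTERTROCH_Z_RANGE[0] <= z_index <= INTERTROCH_Z_RANGE[1]):
        dn = np.asarray(direction) @ cutting_plane.normal
        if abs(dn) > 1e-9:
            t_plane = ((cutting_plane.point - origin) @ cutting_plane.normal) / dn
            if 0 < t_plane < d_surface:
                return float(t_plane)
    return float(d_surface)


def place_radial_points(length_ref_mm: float,
                        target_spacing_mm: float = RADIAL_SPACING_MM
                        ) -> np.ndarray:
    """Radial fractions k/count for a reference ray of given length.

    The interval count comes from the *reference* geometry, so reusing
    it on other femurs preserves correspondence; r=0 is emitted once per
    plane by the cloud builder, not here.
    """
    if target_spacing_mm <= 0:
        raise ValueError("target spacing must be positive")
    if length_ref_mm <= 0:
        return np.array([])
    count = max(1, round(length_ref_mm / target_spacing_mm))
    return np.arange(1, count + 1) / count


def build_cloud(
    frame: FemurFrame,
    outer_mesh: trimesh.Trimesh,
    mask: Volume | None = None,
    config: CloudConfig | None = None,
    case_id: str | None = None,
) -> AtlasPointCloud:
    """Assemble the full point cloud for one femur.

    When ``config.counts`` is empty this femur becomes the reference:
    its ray lengths fix the per-(phi, z) radial counts. Otherwise the
    reference counts are reused so the (z, phi, radial-ordinal) index
    set is identical across femurs; rays that are invalid or points that
    land outside this femur are flagged, never dropped.
    """
    cfg = config or CloudConfig()
    is_reference = cfg.counts is None
    if is_reference:
        cfg = CloudConfig(radial_spacing_mm=cfg.radial_spacing_mm,
                          counts={}, reference_id=case_id)
    caster = _as_caster(outer_mesh)
    stations = discretize_axes(frame, outer_mesh)
    phi_lt = lt_azimuth(frame, stations)
    rows = []
    for st in stations:
        tri_index = caster.plane_triangles(st.origin, st.normal)
        dirs, angles = generate_directions(
            st, frame, lt_azimuth_deg=phi_lt if st.region == "shaft_side"
            else None)
        # axis point, r = 0, once per station
        rows.append((st.z_index, 0, 0, 0.0, *st.origin, st.region, True))
        for phi in range(N_DIRECTIONS):
            length = cast_ray_to_surface(
                st.origin, dirs[phi], caster, frame.cutting_plane,
                st.region, st.z_index, tri_index=tri_index)
            if is_reference:
                if length is None:
                    cfg.counts[(st.z_index, phi)] = 0
                    continue
                fracs = place_radial_points(length, cfg.radial_spacing_mm)
                cfg.counts[(st.z_index, phi)] = len(fracs)
            else:
                count = cfg.counts.get((st.z_index, phi), 0)
                fracs = (np.arange(1, count + 1) / count if count else
                         np.array([]))
            valid = length is not None
            for k, f in enumerate(fracs, start=1):
                if valid:
                    pos = st.origin + f * length * dirs[phi]
                    rows.append((st.z_index, phi, k, float(f), *pos,
                                 st.region, True))
                else:
                    rows.append((st.z_index, phi, k, float(f), np.nan,
                                 np.nan, np.nan, st.region, False))
    df = pd.DataFrame(rows, columns=[
        "z_index", "phi_index", "radial_ordinal", "r", "x", "y", "z",
        "region", "valid"])
    df["inside_bone"] = _inside_flags(df, outer_mesh, mask)
    return AtlasPointCloud(points=df, config=cfg, frame=frame)


def _inside_flags(df: pd.DataFrame, mesh, mask: Volume | None) -> np.ndarray:
    pos = df[["x", "y", "z"]].to_numpy()
    ok = df["valid"].to_numpy() & np.isfinite(pos).all(axis=1)
    inside = np.zeros(len(df), dtype=bool)
    if not ok.any():
        return inside
    pts = pos[ok]
    if mask is not None:
        idx = np.rint(mask.world_to_index(pts)).astype(int)
        in_bounds = np.all((idx >= 0) & (idx < np.array(mask.shape)), axis=1)
        vals = np.zeros(len(pts), dtype=bool)
        ii = idx[in_bounds]
        vals[in_bounds] = np.asarray(mask.data)[ii[:, 0], ii[:, 1], ii[:, 2]] > 0
        inside[np.nonzero(ok)[0]] = vals
    else:
        inside[np.nonzero(ok)[0]] = _as_caster(mesh).contains(pts)
    return inside
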