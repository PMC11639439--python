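"""Vectorized ray-triangle intersection for surface meshes.

A thin batched Moller-Trumbore implementation. Rays used by the cloud
builder all lie in a cross-section plane, so triangles are prefiltered
to the ones crossing that plane, which keeps each station's query small
without any spatial index.
"""

from __future__ import annotations

import numpy as np
import trimesh

__all__ = ["TriangleRayCaster", "surface_distance"]

_EPS = 1e-10


class TriangleRayCaster:
    """All-hits ray caster over a triangle soup."""

    def __init__(self, mesh: trimesh.Trimesh):
        self.triangles = np.asarray(mesh.triangles, dtype=float)  # (F, 3, 3)
        self._v0 = self.triangles[:, 0]
        self._e1 = self.triangles[:, 1] - self._v0
        self._e2 = self.triangles[:, 2] - self._v0

    def _hit_distances(self, origin, direction, tri_index=None) -> np.ndarray:
        """Positive ray parameters of all intersections for one ray."""
        v0 = self._v0 if tri_index is None else self._v0[tri_index]
        e1 = self._e1 if tri_index is None else self._e1[tri_index]
        e2 = self._e2 if tri_index is None else self._e2[tri_index]
        d = np.asarray(direction, dtype=float)
        p = np.cross(d, e2)
        det = np.einsum("ij,ij->i", e1, p)
        ok = np.abs(det) > _EPS
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        s = np.asarray(origin, dtype=float) - v0
        u = np.einsum("ij,ij->i", s, p) * inv
        q = np.cross(s, e1)
        v = (q @ d) * inv
        t = np.einsum("ij,ij->i", e2, q) * inv
        hits = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9) & (t > 1e-9)
        return t[hits]

    def plane_triangles(self, plane_point, plane_normal) -> np.ndarray:
        """Indices of triangles crossing a plane (for in-plane rays)."""
        d = (self.triangles - np.asarray(plane_point)) @ np.asarray(plane_normal)
        return np.nonzero((d.min(axis=1) <= 1e-9) & (d.max(axis=1) >= -1e-9))[0]

    def farthest_hit(self, origin, direction, tri_index=None) -> float | None:
        t = self._hit_distances(origin, direction, tri_index)
        return float(t.max()) if len(t) else None

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Even-odd containment test for a watertight mesh."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.zeros(len(pts), dtype=bool)
        direction = np.array([1.0, 0.0, 0.0])
        for i, p in enumerate(pts):
            out[i] = len(self._hit_distances(p, direction)) % 2 == 1
        return out


def surface_distance(mesh: trimesh.Trimesh, points: np.ndarray,
                     k: int = 40) -> np.ndarray:
    """Unsigned distance from points to the mesh surface.

    Candidate triangles are prefiltered by a KD-tree over triangle
    centroids (k nearest per query point), then resolved with exact
    point-triangle distances.
    """
    from scipy.spatial import cKDTree

    pts = np.atleast_2d(np.asarray(points, dtype=float))
    tris = np.asarray(mesh.triangles, dtype=float)
    tree = cKDTree(tris.mean(axis=1))
    k = min(k, len(tris))
    _, idx = tree.query(pts, k=k)
    idx = np.atleast_2d(idx)
    out = np.empty(len(pts))
    for i, p in enumerate(pts):
        cand = tris[idx[i]]
        closest = trimesh.triangles.closest_point(
            cand, np.repeat(p[None, :], len(cand), axis=0))
        out[i] = np.linalg.norm(closest - p, axis=1).min()
    return out
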