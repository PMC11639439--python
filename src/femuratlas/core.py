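"""Shared geometric containers: volumes, axes, planes.

World coordinates are millimetres in a right-handed frame. Volumes are
stored as ``data[i, j, k]`` with axis order (x, y, z) so that slice ``k``
is one axial CT slice; the affine is diagonal (no oblique acquisitions).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length direction")
    return v / n


@dataclass(frozen=True)
class Axis:
    """A 3D line given by a point and a unit direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "direction", _unit(self.direction))

    def at(self, t: float | np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.point + np.multiply.outer(t, self.direction)

    def project(self, points: np.ndarray) -> np.ndarray:
        """Signed coordinate of ``points`` along the axis direction."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        t = (p - self.point) @ self.direction
        return t if np.asarray(points).ndim > 1 else float(t[0])

    def distance(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        d = p - self.point
        t = d @ self.direction
        perp = d - np.outer(t, self.direction)
        r = np.linalg.norm(perp, axis=1)
        return r if np.asarray(points).ndim > 1 else float(r[0])


@dataclass(frozen=True)
class Plane:
    """A 3D plane given by a point and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "normal", _unit(self.normal))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        d = (p - self.point) @ self.normal
        return d if np.asarray(points).ndim > 1 else float(d[0])


@dataclass
class Volume:
    """A scalar voxel grid with isotropic-axis spacing and world origin.

    ``data[i, j, k]`` sits at world position ``origin + spacing * (i, j, k)``.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive")
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-dimensional")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        a = np.diag(np.append(self.spacing, 1.0))
        a[:3, 3] = self.origin
        return a

    def axes_world(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centers along each grid axis."""
        return tuple(
            self.origin[d] + self.spacing[d] * np.arange(self.shape[d])
            for d in range(3)
        )

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return (p - self.origin) / self.spacing

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return self.origin + idx * self.spacing

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def mirrored_sagittal(self) -> "Volume":
        """Reflect across the world plane x=0 (sagittal mirror)."""
        flipped = self.data[::-1, :, :].copy()
        new_origin = self.origin.copy()
        new_origin[0] = -(self.origin[0] + self.spacing[0] * (self.shape[0] - 1))
        return Volume(flipped, self.spacing.copy(), new_origin)

    def save_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)
        nib.save(img, str(path))

    @classmethod
    def load_nifti(cls, path: str | Path) -> "Volume":
        img = nib.load(str(path))
        aff = img.affine
        spacing = np.diag(aff)[:3].copy()
        origin = aff[:3, 3].copy()
        data = np.asarray(img.dataobj)
        # Normalize negative spacings (flipped storage) to positive.
        for d in range(3):
            if spacing[d] < 0:
                data = np.flip(data, axis=d)
                origin[d] = origin[d] + spacing[d] * (data.shape[d] - 1)
                spacing[d] = -spacing[d]
        return cls(np.ascontiguousarray(data), spacing, origin)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, (Axis, Plane)):
            return dataclasses.asdict(o)
        return super().default(o)


def dump_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, cls=_NumpyEncoder, indent=1, sort_keys=True))


def load_json(path: str | Path):
    return json.loads(Path(path).read_text())
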