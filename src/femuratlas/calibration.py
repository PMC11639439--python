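"""Slice-wise HU-to-BMD calibration from an in-scan six-chamber phantom.

Each axial slice of a QCT acquisition contains the cross-section of a
density calibration rod whose chambers hold known hydroxyapatite
concentrations (0-800 mg/cm^3). Chambers are detected per slice, their
mean HU extracted over a shrunken disc (80 % of the detected radius, to
avoid partial-volume contamination at the rim), and a linear HU-to-BMD
mapping fitted per slice so that tube-current modulation along the table
direction is absorbed slice by slice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from skimage import measure, transform

from .core import Volume
from .synthetic import DEFAULT_CONCENTRATIONS, ChamberLayout

__all__ = [
    "ChamberDetection",
    "CalibrationLine",
    "CalibratedVolume",
    "ChamberDetectionError",
    "detect_chambers",
    "chamber_mean",
    "fit_calibration",
    "apply_calibration",
    "calibrate_volume",
]

CHAMBER_MEAN_FRACTION = 0.80


class ChamberDetectionError(RuntimeError):
    """Raised when fewer than the expected chambers are found in a slice."""


@dataclass(frozen=True)
class ChamberDetection:
    slice_index: int
    centers: np.ndarray  # (6, 2) pixel coordinates (i, j)
    radii: np.ndarray    # (6,) pixels

    def __post_init__(self):
        object.__setattr__(self, "centers", np.asarray(self.centers, dtype=float))
        object.__setattr__(self, "radii", np.asarray(self.radii, dtype=float))
        if np.any(self.radii <= 0):
            raise ValueError("chamber radii must be positive")


@dataclass(frozen=True)
class CalibrationLine:
    """BMD = slope * HU + intercept, with the forward HU(c) fit kept too."""

    slice_index: int
    slope: float
    intercept: float
    r_squared: float
    hu_per_concentration: float = float("nan")
    hu_offset: float = float("nan")


@dataclass
class CalibratedVolume:
    """BMD voxel grid (mg/cm^3) with its femur mask in the same frame."""

    bmd: Volume
    femur_mask: Volume

    def __post_init__(self):
        if self.bmd.shape != self.femur_mask.shape:
            raise ValueError("bmd and femur_mask shapes differ")


def detect_chambers(
    slice_image: np.ndarray,
    layout_hint: ChamberLayout,
    pixel_spacing: float = 1.0,
    slice_index: int = 0,
) -> ChamberDetection:
    """Locate the six chamber discs in one axial slice.

    Primary detector: threshold above the rod body, connected components,
    centroid and equivalent radius per component. If that does not yield
    exactly the expected count, a Hough circle transform around the
    expected radius is tried as a fallback. Chambers are returned
    left-to-right (increasing first image axis), the layout's direction
    of increasing nominal concentration.
    """
    img = np.asarray(slice_image, dtype=float)
    expected_r_px = layout_hint.chamber_radius_mm / pixel_spacing
    thr = layout_hint.detection_threshold_hu
    if thr is None:
        thr = layout_hint.body_hu + 30.0
    binary = img > thr
    labels = measure.label(binary)
    props = measure.regionprops(labels)
    cands = []
    for p in props:
        r_eq = np.sqrt(p.area / np.pi)
        if 0.5 * expected_r_px <= r_eq <= 1.8 * expected_r_px:
            # reject non-circular blobs
            if p.area / (np.pi * r_eq**2 + 1e-9) > 0.85:
                cands.append((p.centroid, r_eq))
    if len(cands) != layout_hint.n_chambers:
        cands = _hough_fallback(img, thr, expected_r_px, layout_hint.n_chambers)
    if cands is None or len(cands) != layout_hint.n_chambers:
        raise ChamberDetectionError(
            f"slice {slice_index}: found {0 if cands is None else len(cands)} "
            f"chambers, expected {layout_hint.n_chambers}")
    cands.sort(key=lambda c: c[0][0])
    centers = np.array([c[0] for c in cands])
    radii = np.array([c[1] for c in cands])
    return ChamberDetection(slice_index, centers, radii)


def _hough_fallback(img, thr, expected_r_px, n):
    edges = np.abs(np.gradient(np.asarray(img > thr, dtype=float))[0]) > 0
    radii_range = np.arange(max(2, int(0.7 * expected_r_px)),
                            int(1.4 * expected_r_px) + 1)
    h = transform.hough_circle(edges, radii_range)
    accums, cx, cy, radii = transform.hough_circle_peaks(
        h, radii_range, total_num_peaks=n,
        min_xdistance=int(expected_r_px), min_ydistance=int(expected_r_px))
    if len(accums) != n:
        return None
    # hough returns (x=col, y=row) in image convention; our slices are (i, j)
    return [((float(y), float(x)), float(r)) for x, y, r in zip(cx, cy, radii)]


def chamber_mean(
    slice_image: np.ndarray,
    detection: ChamberDetection,
    fraction: float = CHAMBER_MEAN_FRACTION,
) -> np.ndarray:
    """Mean HU per chamber over pixels strictly inside ``fraction * radius``.

    Pixel membership is by pixel-center distance, strictly less than the
    shrunken radius; shrinking keeps the partial-volume rim out of the
    average.
    """
    img = np.asarray(slice_image, dtype=float)
    ii, jj = np.meshgrid(np.arange(img.shape[0]), np.arange(img.shape[1]),
                         indexing="ij")
    means = np.empty(len(detection.radii))
    for c, ((ci, cj), r) in enumerate(zip(detection.centers, detection.radii)):
        inside = (ii - ci) ** 2 + (jj - cj) ** 2 < (fraction * r) ** 2
        if not inside.any():
            raise ValueError(
                f"chamber {c}: averaging region empty "
                f"(fraction {fraction}, radius {r:.2f} px)")
        means[c] = img[inside].mean()
    return means


def fit_calibration(
    mean_hu: Sequence[float],
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS,
    slice_index: int = 0,
) -> CalibrationLine:
    """Least-squares line mapping HU to concentration for one slice.

    The applied mapping is the direct concentration-on-HU regression;
    the forward HU-on-concentration fit is reported alongside since the
    two inversions differ slightly under noise.
    """
    hu = np.asarray(mean_hu, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    if hu.shape != conc.shape:
        raise ValueError("mean_hu and concentrations length mismatch")
    if np.ptp(hu) == 0:
        raise ValueError(f"slice {slice_index}: all chamber HU identical, "
                         "degenerate calibration fit")
    inv = stats.linregress(hu, conc)
    fwd = stats.linregress(conc, hu)
    return CalibrationLine(
        slice_index=slice_index,
        slope=float(inv.slope),
        intercept=float(inv.intercept),
        r_squared=float(inv.rvalue ** 2),
        hu_per_concentration=float(fwd.slope),
        hu_offset=float(fwd.intercept),
    )


def apply_calibration(
    hu_volume: Volume,
    lines: Sequence[CalibrationLine | None],
    femur_mask: Volume,
    fill_missing: bool = True,
) -> CalibratedVolume:
    """Map each axial slice to BMD with its own line.

    ``lines[k]`` may be None for slices where detection failed; those
    inherit the nearest valid slice's line when ``fill_missing`` is on,
    otherwise a missing line is an error.
    """
    nz = hu_volume.shape[2]
    if len(lines) != nz:
        raise ValueError(f"need one line per slice: got {len(lines)} for {nz}")
    valid = [k for k, ln in enumerate(lines) if ln is not None]
    if not valid:
        raise ValueError("no valid calibration line in any slice")
    resolved: list[CalibrationLine] = []
    for k in range(nz):
        if lines[k] is not None:
            resolved.append(lines[k])
        elif fill_missing:
            nearest = min(valid, key=lambda v: abs(v - k))
            resolved.append(lines[nearest])
        else:
            raise ValueError(f"missing calibration line for slice {k}")
    slopes = np.array([ln.slope for ln in resolved])
    intercepts = np.array([ln.intercept for ln in resolved])
    bmd = hu_volume.data * slopes[None, None, :] + intercepts[None, None, :]
    return CalibratedVolume(
        bmd=Volume(bmd, hu_volume.spacing.copy(), hu_volume.origin.copy()),
        femur_mask=femur_mask,
    )


def calibrate_volume(
    hu_volume: Volume,
    femur_mask: Volume,
    layout: ChamberLayout,
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS,
    fraction: float = CHAMBER_MEAN_FRACTION,
) -> tuple[CalibratedVolume, list[CalibrationLine | None]]:
    """Full per-slice calibration: detect, average, fit, apply.

    Slices where chamber detection fails get a None line and inherit the
    nearest valid slice's mapping (a warning-level event recorded by the
    pipeline, not an error).
    """
    nz = hu_volume.shape[2]
    px = float(hu_volume.spacing[0])
    lines: list[CalibrationLine | None] = []
    for k in range(nz):
        sl = hu_volume.data[:, :, k]
        try:
            det = detect_chambers(sl, layout, pixel_spacing=px, slice_index=k)
            means = chamber_mean(sl, det, fraction=fraction)
            lines.append(fit_calibration(means, concentrations, slice_index=k))
        except (ChamberDetectionError, ValueError):
            lines.append(None)
    calibrated = apply_calibration(hu_volume, lines, femur_mask)
    return calibrated, lines
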