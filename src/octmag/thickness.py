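"""Full retinal thickness maps from segmented surfaces, and fovea location.

The retina is delimited axially by the inner limiting membrane (ILM) and the
retinal pigment epithelium (RPE); their axial separation along each A-scan is
the full retinal thickness.  The fovea — the pit of minimum thickness — is
located on a lightly smoothed thickness map and refined to sub-pixel
precision, because the central 0.5 mm ETDRS sector is sensitive to centre
placement.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import EyeBiometry, ScanGeometry

__all__ = ["SegmentedSurfaces", "ThicknessMap", "surfaces_to_thickness",
           "locate_fovea"]

log = logging.getLogger(__name__)

#: Hard-error threshold on the fraction of invalid A-scans (segmentation
#: failure rather than isolated dropout).
MAX_INVALID_FRACTION = 0.10


@dataclass
class SegmentedSurfaces:
    """ILM and RPE surface heights on the raster grid.

    Heights are axial positions increasing with depth, either in pixels
    (``unit='px'``, converted via the geometry's axial resolution) or
    directly in micrometres (``unit='um'``).  Missing A-scans are NaN.
    """

    ilm: np.ndarray
    rpe: np.ndarray
    geometry: ScanGeometry
    unit: str = "px"

    def __post_init__(self) -> None:
        self.ilm = np.asarray(self.ilm, dtype=float)
        self.rpe = np.asarray(self.rpe, dtype=float)
        if self.ilm.shape != self.rpe.shape:
            raise ValueError("ILM and RPE grids must share a shape")
        if self.ilm.shape != (self.geometry.n_bscans, self.geometry.n_ascans):
            raise ValueError(
                f"surface shape {self.ilm.shape} does not match geometry "
                f"({self.geometry.n_bscans}, {self.geometry.n_ascans})")
        if self.unit not in ("px", "um"):
            raise ValueError("unit must be 'px' or 'um'")


@dataclass
class ThicknessMap:
    """Per-A-scan full retinal thickness (μm) on the raster grid."""

    thickness: np.ndarray
    geometry: ScanGeometry
    valid_mask: np.ndarray | None = None
    fovea_centre: tuple[float, float] | None = None  # fractional (bscan, ascan)
    biometry: EyeBiometry | None = None

    def __post_init__(self) -> None:
        self.thickness = np.asarray(self.thickness, dtype=float)
        if self.thickness.shape != (self.geometry.n_bscans,
                                    self.geometry.n_ascans):
            raise ValueError("thickness shape does not match geometry")
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.thickness)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.fovea_centre is not None:
            r, c = self.fovea_centre
            nb, na = self.thickness.shape
            if not (0 <= r <= nb - 1 and 0 <= c <= na - 1):
                raise ValueError("fovea_centre outside the grid")


def surfaces_to_thickness(surfaces: SegmentedSurfaces,
                          biometry: EyeBiometry | None = None) -> ThicknessMap:
    """Thickness = (RPE − ILM) per A-scan, converted to μm.

    A-scans where the surfaces cross (RPE not deeper than ILM) or are missing
    are flagged invalid and logged; more than 10% invalid raises, since that
    indicates a failed segmentation rather than local dropout.  No transverse
    smoothing is applied.
    """
    diff = surfaces.rpe - surfaces.ilm
    if surfaces.unit == "px":
        diff = diff * surfaces.geometry.axial_resolution_um
    valid = np.isfinite(diff) & (diff > 0)
    n_invalid = int(diff.size - valid.sum())
    if n_invalid:
        log.info("surfaces_to_thickness: %d/%d invalid A-scans",
                 n_invalid, diff.size)
    if n_invalid / diff.size > MAX_INVALID_FRACTION:
        raise ValueError(
            f"{n_invalid}/{diff.size} A-scans invalid "
            f"(>{MAX_INVALID_FRACTION:.0%}): segmentation failure")
    thickness = np.where(valid, diff, np.nan)
    return ThicknessMap(thickness=thickness, geometry=surfaces.geometry,
                        valid_mask=valid, biometry=biometry)


def _nan_uniform_smooth(values: np.ndarray, valid: np.ndarray,
                        size: tuple[int, int]) -> np.ndarray:
    """Moving-average smoothing that ignores invalid pixels."""
    filled = np.where(valid, values, 0.0)
    num = ndimage.uniform_filter(filled, size=size, mode="nearest")
    den = ndimage.uniform_filter(valid.astype(float), size=size,
                                 mode="nearest")
    with np.errstate(invalid="ignore"):
        out = num / den
    out[den <= 0] = np.nan
    return out


def _parabolic_offset(fm: float, f0: float, fp: float) -> float:
    """Sub-pixel offset of a parabola through three equispaced samples."""
    denom = fm - 2.0 * f0 + fp
    if denom <= 0 or not math.isfinite(denom):
        return 0.0
    return float(np.clip(0.5 * (fm - fp) / denom, -0.5, 0.5))


def locate_fovea(tmap: ThicknessMap, search_radius_mm: float = 1.5,
                 smooth_mm: float = 0.25) -> tuple[float, float]:
    """Locate the foveal centre as the minimum of the smoothed thickness map.

    The search is restricted to ``search_radius_mm`` around the scan centre
    (the acquisition protocol centres scans on the fovea, so a wider search
    invites ectopic minima such as truncated peripheral thinning).  Distances
    use the device-default scales: the search happens in raw image space
    before any magnification handling.  Ties are broken toward the scan
    centre; the discrete minimum is refined by separable quadratic
    interpolation.

    Returns fractional (bscan, ascan) coordinates.
    """
    geom = tmap.geometry
    sx, sy = geom.scale_x_default, geom.scale_y_default
    kx = max(1, int(round(smooth_mm / sx)) | 1)
    ky = max(1, int(round(smooth_mm / sy)) | 1)
    smooth = _nan_uniform_smooth(tmap.thickness, tmap.valid_mask, (ky, kx))

    cy, cx = geom.centre
    rows = np.arange(geom.n_bscans)[:, None]
    cols = np.arange(geom.n_ascans)[None, :]
    dist2 = ((cols - cx) * sx) ** 2 + ((rows - cy) * sy) ** 2
    in_window = (dist2 <= search_radius_mm**2) & np.isfinite(smooth)
    if not in_window.any():
        raise ValueError("no valid pixels within the fovea search window")

    cost = np.where(in_window, smooth, np.inf)
    vmin = cost.min()
    # tie-break: among (near-)minimal pixels pick the one closest to centre
    cand = np.argwhere(cost <= vmin + 1e-12)
    order = np.argsort(dist2[cand[:, 0], cand[:, 1]], kind="stable")
    i0, j0 = (int(v) for v in cand[order[0]])

    di = dj = 0.0
    if 0 < i0 < geom.n_bscans - 1 and np.isfinite(smooth[i0 - 1, j0]) \
            and np.isfinite(smooth[i0 + 1, j0]):
        di = _parabolic_offset(smooth[i0 - 1, j0], smooth[i0, j0],
                               smooth[i0 + 1, j0])
    if 0 < j0 < geom.n_ascans - 1 and np.isfinite(smooth[i0, j0 - 1]) \
            and np.isfinite(smooth[i0, j0 + 1]):
        dj = _parabolic_offset(smooth[i0, j0 - 1], smooth[i0, j0],
                               smooth[i0, j0 + 1])
    return (i0 + di, j0 + dj)
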