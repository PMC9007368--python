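"""ETDRS grid construction in scan-pixel coordinates and sector averaging.

The ETDRS layout is a central disc of 0.5 mm radius plus inner (0.5–1.5 mm)
and outer (1.5–3.0 mm) annuli, each annulus split into superior, inferior,
nasal and temporal quadrants at the ±45° diagonals — nine sectors.  The grid
is placed on the raster in physical millimetres; the raw grid uses the
device-default transverse scales, the corrected grid uses the axial-length
corrected scales.  The correction is purely a region-placement change: the
thickness values themselves are never resampled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import EyeBiometry, ScanGeometry
from .thickness import SegmentedSurfaces, ThicknessMap, locate_fovea, \
    surfaces_to_thickness

__all__ = ["SECTORS", "ETDRS_RADII_MM", "EtdrsSectorSet", "SectorThickness",
           "label_points", "build_grid", "sector_means", "extract_eye",
           "default_nasal_side"]

#: Sector names: central, then inner ring, then outer ring.
SECTORS = ("C", "N1", "S1", "T1", "I1", "N2", "S2", "T2", "I2")
OUTSIDE = len(SECTORS)  # label for pixels beyond 3 mm

#: Ring boundary radii in mm (central disc, inner ring, outer ring).
ETDRS_RADII_MM = (0.5, 1.5, 3.0)

_QUADRANTS = ("N", "S", "T", "I")


def default_nasal_side(eye: str) -> str:
    """Image side holding the nasal retina, per laterality.

    With en-face images displayed as the examiner sees the patient, the
    nasal retina (the side toward the nose, nearer the optic disc) is on the
    image right for OD and the image left for OS.  Configurable wherever it
    is consumed, since export conventions vary.
    """
    if eye == "OD":
        return "right"
    if eye == "OS":
        return "left"
    raise ValueError(f"eye must be 'OD' or 'OS', got {eye!r}")


def label_points(x_nasal: np.ndarray, y_sup: np.ndarray,
                 radii: tuple[float, float, float] = ETDRS_RADII_MM,
                 ) -> np.ndarray:
    """ETDRS sector label for points in fovea-centred retinal coordinates.

    ``x_nasal`` increases toward the nasal retina, ``y_sup`` toward the
    superior retina, both in mm.  Radius bins are half-open ([0, 0.5),
    [0.5, 1.5), [1.5, 3.0)); the ±45° diagonals belong to the horizontal
    (nasal/temporal) quadrants.  Returns integer labels indexing ``SECTORS``,
    with ``OUTSIDE`` beyond the outer radius.
    """
    x = np.asarray(x_nasal, dtype=float)
    y = np.asarray(y_sup, dtype=float)
    r = np.hypot(x, y)
    r0, r1, r2 = radii

    labels = np.full(r.shape, OUTSIDE, dtype=np.int8)
    labels[r < r0] = SECTORS.index("C")

    ax, ay = np.abs(x), np.abs(y)
    horizontal = ax >= ay  # diagonals inclusive to nasal/temporal
    quad = np.where(horizontal, np.where(x >= 0, 0, 2),   # N, T
                    np.where(y > 0, 1, 3))                # S, I
    inner = (r >= r0) & (r < r1)
    outer = (r >= r1) & (r < r2)
    for qi, qname in enumerate(_QUADRANTS):
        labels[inner & (quad == qi)] = SECTORS.index(qname + "1")
        labels[outer & (quad == qi)] = SECTORS.index(qname + "2")
    return labels


@dataclass
class EtdrsSectorSet:
    """Per-pixel sector labels on a raster grid, plus the placement used."""

    labels: np.ndarray  # int8, values in 0..8 or OUTSIDE
    centre: tuple[float, float]  # fractional (bscan, ascan)
    scale_x: float
    scale_y: float
    laterality: str
    nasal_side: str
    corrected: bool
    radii: tuple[float, float, float] = ETDRS_RADII_MM
    truncation: dict[str, float] = field(default_factory=dict)

    def mask(self, sector: str) -> np.ndarray:
        return self.labels == SECTORS.index(sector)

    @property
    def masks(self) -> dict[str, np.ndarray]:
        return {s: self.mask(s) for s in SECTORS}


@dataclass
class SectorThickness:
    """Mean thickness (μm) and pixel count per ETDRS sector for one eye."""

    means: dict[str, float]
    counts: dict[str, int]
    corrected: bool
    biometry: EyeBiometry | None = None
    truncation: dict[str, float] = field(default_factory=dict)


def _sector_area_mm2(radii: tuple[float, float, float]) -> dict[str, float]:
    r0, r1, r2 = radii
    areas = {"C": np.pi * r0**2}
    for q in _QUADRANTS:
        areas[q + "1"] = np.pi * (r1**2 - r0**2) / 4
        areas[q + "2"] = np.pi * (r2**2 - r1**2) / 4
    return areas


def build_grid(geometry: ScanGeometry, biometry: EyeBiometry,
               centre: tuple[float, float], corrected: bool,
               nasal_side: str | None = None,
               truncation_warn: float = 0.20) -> EtdrsSectorSet:
    """Assign every raster pixel to an ETDRS sector.

    Pixel (i, j) sits at physical offset ((j−cx)·sx, (i−cy)·sy) from the
    foveal centre, where (sx, sy) are the device-default scales when
    ``corrected`` is false and the axial-length corrected scales otherwise.
    Membership is a pixel-centre point-in-region test (no area weighting),
    matching per-A-scan thickness extraction.

    A per-sector truncation fraction (sector area falling outside the
    scanned field, estimated from the pixel-count deficit) is reported;
    sectors truncated by more than ``truncation_warn`` trigger a warning.
    """
    cy, cx = centre
    if not (0 <= cy <= geometry.n_bscans - 1 and
            0 <= cx <= geometry.n_ascans - 1):
        raise ValueError(f"grid centre {centre} outside the raster")
    sx, sy = geometry.scales_for(
        biometry.axial_length if corrected else None, corrected)
    side = nasal_side or default_nasal_side(biometry.eye)
    if side not in ("left", "right"):
        raise ValueError("nasal_side must be 'left' or 'right'")

    rows = np.arange(geometry.n_bscans, dtype=float)[:, None]
    cols = np.arange(geometry.n_ascans, dtype=float)[None, :]
    dx = (cols - cx) * sx
    dy = (rows - cy) * sy
    x_nasal = dx if side == "right" else -dx
    y_sup = -dy + np.zeros_like(x_nasal)  # row index grows downward (inferior)
    labels = label_points(x_nasal, y_sup)

    counts = np.bincount(labels.ravel(), minlength=OUTSIDE + 1)
    px_area = sx * sy
    # distance from the grid centre to the nearest field edge: a sector whose
    # outer radius stays inside it cannot be truncated, whatever the (noisy,
    # on coarse rasters) pixel-count coverage estimate says
    d_edge = min(cx * sx, (geometry.n_ascans - 1 - cx) * sx,
                 cy * sy, (geometry.n_bscans - 1 - cy) * sy)
    outer_radius = {"C": ETDRS_RADII_MM[0]}
    outer_radius.update({q + "1": ETDRS_RADII_MM[1] for q in _QUADRANTS})
    outer_radius.update({q + "2": ETDRS_RADII_MM[2] for q in _QUADRANTS})
    truncation: dict[str, float] = {}
    for name, area in _sector_area_mm2(ETDRS_RADII_MM).items():
        if outer_radius[name] <= d_edge:
            truncation[name] = 0.0
            continue
        covered = counts[SECTORS.index(name)] * px_area / area
        truncation[name] = float(np.clip(1.0 - covered, 0.0, 1.0))
    worst = max(truncation, key=truncation.get)
    if truncation[worst] > truncation_warn:
        warnings.warn(
            f"sector {worst} truncated by {truncation[worst]:.0%} "
            f"of its area by the scan bounds", stacklevel=2)
    return EtdrsSectorSet(labels=labels, centre=(cy, cx), scale_x=sx,
                          scale_y=sy, laterality=biometry.eye,
                          nasal_side=side, corrected=corrected,
                          truncation=truncation)


def sector_means(tmap: ThicknessMap, sectors: EtdrsSectorSet,
                 ) -> SectorThickness:
    """Unweighted mean of valid pixels per sector; invalid pixels excluded."""
    if tmap.thickness.shape != sectors.labels.shape:
        raise ValueError("thickness map and sector masks differ in shape")
    valid = sectors.labels[tmap.valid_mask]
    vals = tmap.thickness[tmap.valid_mask]
    counts = np.bincount(valid.ravel(), minlength=OUTSIDE + 1)
    sums = np.bincount(valid.ravel(), weights=vals.ravel(),
                       minlength=OUTSIDE + 1)
    means: dict[str, float] = {}
    out_counts: dict[str, int] = {}
    for k, name in enumerate(SECTORS):
        if counts[k] == 0:
            raise ValueError(f"sector {name} has no valid pixels")
        means[name] = float(sums[k] / counts[k])
        out_counts[name] = int(counts[k])
    return SectorThickness(means=means, counts=out_counts,
                           corrected=sectors.corrected,
                           biometry=tmap.biometry,
                           truncation=dict(sectors.truncation))


def extract_eye(source: ThicknessMap | SegmentedSurfaces,
                biometry: EyeBiometry,
                geometry: ScanGeometry | None = None,
                nasal_side: str | None = None,
                search_radius_mm: float = 1.5,
                smooth_mm: float = 0.25,
                ) -> tuple[SectorThickness, SectorThickness]:
    """Raw and corrected sector means for one eye.

    Both variants share the same thickness map and the same detected foveal
    centre; they differ only in the transverse scale used to place the grid.
    Returns ``(raw, corrected)``.
    """
    if isinstance(source, SegmentedSurfaces):
        tmap = surfaces_to_thickness(source, biometry=biometry)
    else:
        tmap = source
    geometry = geometry or tmap.geometry
    centre = locate_fovea(tmap, search_radius_mm=search_radius_mm,
                          smooth_mm=smooth_mm)
    tmap.fovea_centre = centre
    results = []
    for corrected in (False, True):
        grid = build_grid(geometry, biometry, centre, corrected,
                          nasal_side=nasal_side)
        results.append(sector_means(tmap, grid))
    return results[0], results[1]
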