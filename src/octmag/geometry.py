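"""Scan geometry, eye biometry and the axial-length magnification correction.

SD-OCT devices convert scan angle to retinal millimetres using a fixed
schematic eye.  The Spectralis assumes an axial length of 24.385 mm; eyes
longer than that image a larger retinal area than the device-reported
transverse scale implies, shorter eyes a smaller one.  The correction applied
throughout this package rescales the device transverse scale by the ratio of
the measured axial length to the device default::

    corrected_scale = default_scale * axial_length / assumed_axial_length

Corneal-curvature magnification is assumed to be handled device-side (the
reported "Scaling X" already reflects it) and is deliberately not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "SPECTRALIS_ASSUMED_AL_MM",
    "CIRRUS_ASSUMED_AL_MM",
    "COPERNICUS_ASSUMED_AL_MM",
    "AL_PLAUSIBLE_MM",
    "SNR_MIN",
    "ScanGeometry",
    "EyeBiometry",
    "corrected_transverse_scale",
    "actual_scan_extent",
    "spherical_equivalent",
    "classify_refractive_group",
    "quality_filter",
]

#: Schematic-eye axial length assumed by the Heidelberg Spectralis (mm).
SPECTRALIS_ASSUMED_AL_MM = 24.385
#: Alternates for other common devices (documented, not used by default).
CIRRUS_ASSUMED_AL_MM = 24.46
COPERNICUS_ASSUMED_AL_MM = 24.00

#: Plausibility gate for measured axial length (mm).  A value outside this
#: range almost certainly indicates a unit mistake (e.g. metres or microns)
#: and would silently corrupt every downstream sector, so it is a hard error.
AL_PLAUSIBLE_MM = (15.0, 35.0)

#: Scans with device signal-to-noise below this score are discarded.
SNR_MIN = 20.0


def _validate_axial_length(axial_length: float) -> None:
    lo, hi = AL_PLAUSIBLE_MM
    if not (math.isfinite(axial_length) and lo <= axial_length <= hi):
        raise ValueError(
            f"axial_length={axial_length!r} mm is outside the plausible range "
            f"[{lo}, {hi}] mm; check units (expected millimetres)"
        )


@dataclass(frozen=True)
class ScanGeometry:
    """Device-reported raster geometry of a macular volume scan.

    Defaults mirror a Spectralis 31-line raster over a 30° x 25° field,
    laterally downsampled to 512 A-scans per B-scan.

    Parameters
    ----------
    n_bscans, n_ascans
        Raster dimensions (B-scans are rows, A-scans columns).
    scale_x_default
        Device-reported transverse scale along a B-scan ("Scaling X"),
        mm per pixel, valid only for an eye of ``assumed_axial_length``.
    scale_y_default
        Distance between adjacent B-scans, mm, under the same assumption.
    axial_resolution_um
        Axial sampling, micrometres per pixel.
    assumed_axial_length
        Schematic-eye axial length baked into the device scales, mm.
    """

    n_bscans: int = 31
    n_ascans: int = 512
    scale_x_default: float = 8.64 / 511
    scale_y_default: float = 7.20 / 30
    axial_resolution_um: float = 3.9
    assumed_axial_length: float = SPECTRALIS_ASSUMED_AL_MM

    def __post_init__(self) -> None:
        if self.n_bscans < 1 or self.n_ascans < 1:
            raise ValueError("raster dimensions must be positive")
        for name in ("scale_x_default", "scale_y_default",
                     "axial_resolution_um", "assumed_axial_length"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def nominal_extent_x(self) -> float:
        """Nominal horizontal extent (mm) between outermost A-scan centres."""
        return (self.n_ascans - 1) * self.scale_x_default

    @property
    def nominal_extent_y(self) -> float:
        """Nominal vertical extent (mm) between first and last B-scan."""
        return (self.n_bscans - 1) * self.scale_y_default

    @property
    def centre(self) -> tuple[float, float]:
        """Grid centre as fractional (bscan, ascan) coordinates."""
        return ((self.n_bscans - 1) / 2.0, (self.n_ascans - 1) / 2.0)

    def scales_for(self, axial_length: float | None,
                   corrected: bool) -> tuple[float, float]:
        """(scale_x, scale_y) in mm/px, optionally magnification-corrected.

        The axial-length ratio acts on visual angle and is therefore
        isotropic in the transverse plane: both directions are rescaled.
        """
        if not corrected:
            return self.scale_x_default, self.scale_y_default
        if axial_length is None:
            raise ValueError("axial_length is required for corrected scales")
        sx = corrected_transverse_scale(self.scale_x_default, axial_length,
                                        self.assumed_axial_length)
        sy = corrected_transverse_scale(self.scale_y_default, axial_length,
                                        self.assumed_axial_length)
        return sx, sy


@dataclass(frozen=True)
class EyeBiometry:
    """Per-eye biometry and refraction.

    ``sphere``/``cylinder`` are in dioptres with a minus-cylinder convention;
    set ``plus_cylinder=True`` to convert plus-cylinder input on creation.
    ``corneal_radius`` is carried as metadata only: the device corrects
    corneal-curvature magnification internally.
    """

    participant_id: str
    eye: str  # "OD" | "OS"
    axial_length: float
    sphere: float = 0.0
    cylinder: float = 0.0
    corneal_radius: float | None = None
    snr: float | None = None
    sex: str | None = None
    ethnicity: str | None = None
    plus_cylinder: bool = False

    def __post_init__(self) -> None:
        if self.eye not in ("OD", "OS"):
            raise ValueError(f"eye must be 'OD' or 'OS', got {self.eye!r}")
        _validate_axial_length(self.axial_length)
        if self.plus_cylinder:
            # normalise to minus-cylinder form: transpose the cross cylinder
            object.__setattr__(self, "sphere", self.sphere + self.cylinder)
            object.__setattr__(self, "cylinder", -self.cylinder)
            object.__setattr__(self, "plus_cylinder", False)

    @property
    def spherical_equivalent(self) -> float:
        return spherical_equivalent(self.sphere, self.cylinder)

    @property
    def refractive_group(self) -> str:
        return classify_refractive_group(self.spherical_equivalent)


def corrected_transverse_scale(scale_default: float, axial_length: float,
                               assumed_axial_length: float = SPECTRALIS_ASSUMED_AL_MM,
                               ) -> float:
    """Magnification-corrected transverse scale, mm per pixel.

    ``scale_default * axial_length / assumed_axial_length``: the true
    on-retina pixel pitch for an eye of the given axial length, given the
    pitch the device reports for its schematic eye.
    """
    if not scale_default > 0:
        raise ValueError("scale_default must be strictly positive")
    if not assumed_axial_length > 0:
        raise ValueError("assumed_axial_length must be strictly positive")
    _validate_axial_length(axial_length)
    return scale_default * axial_length / assumed_axial_length


def actual_scan_extent(nominal_extent: float, axial_length: float,
                       assumed_axial_length: float = SPECTRALIS_ASSUMED_AL_MM,
                       ) -> float:
    """True on-retina extent (mm) of a scan with the given nominal extent."""
    if not nominal_extent > 0:
        raise ValueError("nominal_extent must be strictly positive")
    return corrected_transverse_scale(nominal_extent, axial_length,
                                      assumed_axial_length)


def spherical_equivalent(sphere: float, cylinder: float) -> float:
    """Spherical equivalent refraction: sphere + cylinder / 2, dioptres."""
    if not (math.isfinite(sphere) and math.isfinite(cylinder)):
        raise ValueError("sphere and cylinder must be finite")
    return sphere + cylinder / 2.0


def classify_refractive_group(se: float) -> str:
    """'myope' if spherical equivalent <= -0.50 D, else 'non-myope'."""
    if not math.isfinite(se):
        raise ValueError("spherical equivalent must be finite")
    return "myope" if se <= -0.50 else "non-myope"


def quality_filter(eyes: Iterable[EyeBiometry],
                   snr_min: float = SNR_MIN,
                   ) -> tuple[list[EyeBiometry], list[dict]]:
    """Drop scans of inadequate quality (SNR below ``snr_min``).

    Returns the retained records and an exclusion log with one entry per
    dropped record (``participant_id``, ``eye``, ``reason``).  A missing SNR
    is logged as ``missing_snr`` and excluded rather than raising.
    """
    retained: list[EyeBiometry] = []
    excluded: list[dict] = []
    for rec in eyes:
        if rec.snr is None or not math.isfinite(rec.snr):
            excluded.append({"participant_id": rec.participant_id,
                             "eye": rec.eye, "reason": "missing_snr"})
        elif rec.snr < snr_min:
            excluded.append({"participant_id": rec.participant_id,
                             "eye": rec.eye,
                             "reason": f"snr_below_{snr_min:g}",
                             "snr": rec.snr})
        else:
            retained.append(rec)
    return retained, excluded
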