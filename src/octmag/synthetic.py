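"""Synthetic foveal-pit retinas, a magnifying scanner, and two-eyed cohorts.

The ground-truth retina is a smooth radial thickness profile: a peripheral
baseline, a parafoveal bump (the retina is thickest in the parafovea), and a
central Gaussian pit (difference of Gaussians)::

    T(r) = t_periphery + a_para * exp(-(r - r_peak)^2 / (2 sigma_para^2))
                       - a_pit  * exp(-r^2 / (2 sigma_pit^2))

The simulated scanner samples this surface at the TRUE on-retina positions
(pixel pitch scaled by axial_length / assumed_axial_length) but stamps the
output with the device-default scales — reproducing the transverse
magnification error exactly as a real instrument does.  Cohorts draw
correlated per-eye axial lengths, map axial length to spherical equivalent
(a crude, explicitly non-biological emmetropization-failure model, there
only to produce realistic myope/non-myope groups), and add participant- and
eye-level thickness offsets so the paired-eye mixed models downstream have
real correlation structure to absorb.

Ground truth for any sector is available by Gauss–Legendre quadrature of the
continuous profile over the exact sector boundaries; the same oracle with
boundaries shrunk or dilated by the axial-length ratio predicts what the raw
(uncorrected) grid measures.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .etdrs import ETDRS_RADII_MM, SECTORS, default_nasal_side
from .geometry import EyeBiometry, ScanGeometry, SPECTRALIS_ASSUMED_AL_MM, \
    classify_refractive_group
from .thickness import SegmentedSurfaces, ThicknessMap

__all__ = ["PitModel", "CohortSpec", "pit_thickness", "simulate_scan",
           "draw_biometry", "simulate_cohort", "sector_mean_quadrature",
           "true_sector_means", "magnification_bias", "scan_to_surfaces"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PitModel:
    """Parameters of the continuous ground-truth thickness surface.

    Defaults put sector means in the plausible 250–340 μm range for a young
    healthy macula; they are configuration, not normative values.

    Parameters
    ----------
    t_periphery : float
        Baseline thickness far from the fovea, μm.
    a_para, r_peak, sigma_para : float
        Amplitude (μm), radius (mm) and width (mm) of the parafoveal bump.
    a_pit, sigma_pit : float
        Depth (μm) and width (mm) of the central pit.
    nasal_asymmetry : float
        Multiplier on the parafoveal bump amplitude on the nasal half-plane
        (blended smoothly across the vertical midline); 1.0 = symmetric.
    al_slope_central, al_slope_peripheral : float
        Optional biological thinning, μm per mm of axial length above
        ``al_reference``, applied with a pit-shaped radial weight (central
        slope at the fovea, peripheral slope outside).  Zero by default: the
        baseline cohort carries magnification effects only.
    """

    t_periphery: float = 290.0
    a_para: float = 50.0
    r_peak: float = 1.3
    sigma_para: float = 0.9
    a_pit: float = 120.0
    sigma_pit: float = 0.35
    nasal_asymmetry: float = 1.0
    al_slope_central: float = 0.0
    al_slope_peripheral: float = 0.0
    al_reference: float = SPECTRALIS_ASSUMED_AL_MM
    asymmetry_blend_mm: float = 0.25

    def __post_init__(self) -> None:
        if not (0.5 < self.r_peak < 2.5):
            raise ValueError("r_peak must sit in (0.5, 2.5) mm (parafovea)")
        for name in ("t_periphery", "sigma_para", "sigma_pit",
                     "asymmetry_blend_mm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.a_pit < 0 or self.a_para < 0:
            raise ValueError("amplitudes must be non-negative")


def pit_thickness(model: PitModel, x: np.ndarray | float,
                  y: np.ndarray | float, axial_length: float | None = None,
                  ) -> np.ndarray | float:
    """Ground-truth thickness (μm) at fovea-centred retinal position (x, y).

    ``x`` increases toward the nasal retina, ``y`` toward the superior
    retina, both in mm.  Deterministic and smooth; radially symmetric when
    ``nasal_asymmetry`` is 1.  ``axial_length`` only matters when the model
    carries biological AL slopes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r2 = x * x + y * y
    r = np.sqrt(r2)
    bump = np.exp(-((r - model.r_peak) ** 2) / (2 * model.sigma_para**2))
    if model.nasal_asymmetry != 1.0:
        blend = expit(x / model.asymmetry_blend_mm)
        bump = bump * (1.0 + (model.nasal_asymmetry - 1.0) * blend)
    pit = np.exp(-r2 / (2 * model.sigma_pit**2))
    t = model.t_periphery + model.a_para * bump - model.a_pit * pit
    if axial_length is not None and (model.al_slope_central
                                     or model.al_slope_peripheral):
        dal = axial_length - model.al_reference
        w_central = np.exp(-r2 / (2 * model.sigma_pit**2))
        t = t + dal * (model.al_slope_central * w_central
                       + model.al_slope_peripheral * (1.0 - w_central))
    return t if np.ndim(t) else float(t)


def _scan_positions(geometry: ScanGeometry, axial_length: float,
                    nasal_side: str,
                    fovea_offset_mm: tuple[float, float] = (0.0, 0.0),
                    ) -> tuple[np.ndarray, np.ndarray]:
    """True on-retina (x_nasal, y_sup) mm of every pixel, fovea at origin.

    The pixel pitch is the device default scaled by AL/assumed — the actual
    field of view.  ``fovea_offset_mm`` displaces the pit relative to the
    scan centre (image-right, image-down components).
    """
    sx = geometry.scale_x_default * axial_length / geometry.assumed_axial_length
    sy = geometry.scale_y_default * axial_length / geometry.assumed_axial_length
    cy, cx = geometry.centre
    cols = (np.arange(geometry.n_ascans) - cx) * sx
    rows = (np.arange(geometry.n_bscans) - cy) * sy
    dx = cols[None, :] - fovea_offset_mm[0]
    dy = rows[:, None] - fovea_offset_mm[1]
    x_img = np.broadcast_to(dx, (geometry.n_bscans, geometry.n_ascans))
    y_img = np.broadcast_to(dy, (geometry.n_bscans, geometry.n_ascans))
    x_nasal = x_img if nasal_side == "right" else -x_img
    return x_nasal, -y_img


def simulate_scan(model: PitModel, geometry: ScanGeometry,
                  biometry: EyeBiometry, noise_sd: float = 0.0,
                  seed: int | np.random.Generator | None = 0,
                  fovea_offset_mm: tuple[float, float] = (0.0, 0.0),
                  thickness_offset: float = 0.0,
                  nasal_side: str | None = None) -> ThicknessMap:
    """Simulate one macular raster scan of a synthetic eye.

    Samples the continuous surface at the eye's TRUE pixel positions (field
    of view scaled by the axial-length ratio), adds i.i.d. Gaussian
    measurement noise, and returns a map stamped with the DEVICE-default
    geometry — i.e. carrying the same magnification error a real scanner
    produces.  Fully reproducible for a fixed seed.
    """
    side = nasal_side or default_nasal_side(biometry.eye)
    x_nasal, y_sup = _scan_positions(geometry, biometry.axial_length, side,
                                     fovea_offset_mm)
    t = pit_thickness(model, x_nasal, y_sup, biometry.axial_length)
    t = t + thickness_offset
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        t = t + rng.normal(0.0, noise_sd, size=t.shape)
    # the true fovea position in (fractional) pixel units of the stamped grid
    sx_true = geometry.scale_x_default * biometry.axial_length \
        / geometry.assumed_axial_length
    sy_true = geometry.scale_y_default * biometry.axial_length \
        / geometry.assumed_axial_length
    cy, cx = geometry.centre
    centre = (cy + fovea_offset_mm[1] / sy_true,
              cx + fovea_offset_mm[0] / sx_true)
    return ThicknessMap(thickness=np.ascontiguousarray(t), geometry=geometry,
                        fovea_centre=centre, biometry=biometry)


def scan_to_surfaces(tmap: ThicknessMap, ilm_depth_px: float = 100.0,
                     ) -> SegmentedSurfaces:
    """Re-express a thickness map as ILM/RPE surfaces (pixel heights).

    The ILM is placed at a constant depth; the RPE follows at
    thickness / axial_resolution below it.  Lets synthetic data exercise the
    same surfaces-to-thickness path real segmentations take.
    """
    ilm = np.full_like(tmap.thickness, ilm_depth_px)
    rpe = ilm + tmap.thickness / tmap.geometry.axial_resolution_um
    return SegmentedSurfaces(ilm=ilm, rpe=rpe, geometry=tmap.geometry,
                             unit="px")


# ---------------------------------------------------------------------------
# Quadrature oracle


def _quadrant_theta(sector: str) -> tuple[float, float]:
    # angles from the +x (nasal) axis, CCW; diagonals at +/-45 deg
    spans = {"N": (-math.pi / 4, math.pi / 4),
             "S": (math.pi / 4, 3 * math.pi / 4),
             "T": (3 * math.pi / 4, 5 * math.pi / 4),
             "I": (5 * math.pi / 4, 7 * math.pi / 4)}
    return spans[sector[0]]


def sector_mean_quadrature(model: PitModel, sector: str,
                           axial_length: float | None = None,
                           grid: str = "corrected",
                           assumed_axial_length: float = SPECTRALIS_ASSUMED_AL_MM,
                           thickness_offset: float = 0.0,
                           n_r: int = 96, n_theta: int = 96) -> float:
    """Area-weighted mean of the continuous profile over one ETDRS sector.

    ``grid='corrected'`` integrates over the sector's true boundaries —
    ground truth.  ``grid='raw'`` dilates the radial boundaries by
    AL/assumed: the region a magnification-uncorrected grid actually
    averages over (the raw grid's nominal radius r spans true radius
    r × AL/assumed on the retina).  Gauss–Legendre in r and θ with the polar
    area element.
    """
    if sector not in SECTORS:
        raise ValueError(f"unknown sector {sector!r}")
    if grid not in ("corrected", "raw"):
        raise ValueError("grid must be 'corrected' or 'raw'")
    r0_, r1_, r2_ = ETDRS_RADII_MM
    if sector == "C":
        rlo, rhi = 0.0, r0_
        tlo, thi = 0.0, 2 * math.pi
    else:
        rlo, rhi = (r0_, r1_) if sector.endswith("1") else (r1_, r2_)
        tlo, thi = _quadrant_theta(sector)
    if grid == "raw":
        if axial_length is None:
            raise ValueError("axial_length required for the raw grid")
        k = axial_length / assumed_axial_length
        rlo, rhi = rlo * k, rhi * k

    xr, wr = np.polynomial.legendre.leggauss(n_r)
    xt, wt = np.polynomial.legendre.leggauss(n_theta)
    r = 0.5 * (rhi - rlo) * xr + 0.5 * (rhi + rlo)
    th = 0.5 * (thi - tlo) * xt + 0.5 * (thi + tlo)
    rg, tg = np.meshgrid(r, th, indexing="ij")
    wg = np.outer(wr, wt) * rg  # polar area element
    x = rg * np.cos(tg)
    y = rg * np.sin(tg)
    vals = pit_thickness(model, x, y, axial_length) + thickness_offset
    return float(np.sum(wg * vals) / np.sum(wg))


def true_sector_means(model: PitModel, axial_length: float | None = None,
                      thickness_offset: float = 0.0,
                      **kwargs) -> dict[str, float]:
    """Ground-truth mean per sector (quadrature over true boundaries)."""
    return {s: sector_mean_quadrature(model, s, axial_length,
                                      grid="corrected",
                                      thickness_offset=thickness_offset,
                                      **kwargs)
            for s in SECTORS}


def magnification_bias(model: PitModel, axial_length: float, sector: str,
                       assumed_axial_length: float = SPECTRALIS_ASSUMED_AL_MM,
                       ) -> float:
    """Raw-grid minus true sector mean (μm) for one eye: the error the
    axial-length correction removes."""
    raw = sector_mean_quadrature(model, sector, axial_length, grid="raw",
                                 assumed_axial_length=assumed_axial_length)
    true = sector_mean_quadrature(model, sector, axial_length,
                                  grid="corrected")
    return raw - true


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass(frozen=True)
class CohortSpec:
    """Configuration of a two-eyed synthetic cohort.

    Defaults mirror a community-based young-adult sample: axial length
    N(23.6, 0.9²) mm with high interocular correlation and roughly 23%
    myopes (spherical equivalent ≤ −0.50 D) arising from a linear AL→SE
    mapping with refraction noise.
    """

    n_participants: int = 100
    al_mean: float = 23.6
    al_sd: float = 0.9
    interocular_al_correlation: float = 0.95
    myope_fraction_target: float = 0.23
    se_from_al_slope: float = -1.5     # D per mm of AL
    al_emmetropia: float = 24.0        # AL at which the mapping crosses 0 D
    se_noise_shared_sd: float = 0.65   # D, participant-level refraction noise
    se_noise_eye_sd: float = 0.35      # D, eye-level refraction noise
    sex_effect: float = 5.0            # μm added for males
    participant_sd: float = 12.0       # μm, shared between the two eyes
    eye_sd: float = 4.0                # μm, eye-specific
    myope_thinning: float = 0.0        # μm true biological group effect
    noise_sd: float = 3.0              # μm per-A-scan measurement noise
    fixation_jitter_mm: float = 0.10   # sd of fovea-to-raster misalignment
    ethnicity_probs: tuple[float, float, float] = (0.86, 0.02, 0.12)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if min(self.al_sd, self.noise_sd, self.se_noise_shared_sd,
               self.se_noise_eye_sd) < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0.0 <= self.interocular_al_correlation <= 1.0:
            raise ValueError("interocular correlation must lie in [0, 1]")
        if not math.isclose(sum(self.ethnicity_probs), 1.0, abs_tol=1e-9):
            raise ValueError("ethnicity_probs must sum to 1")


_ETHNICITIES = ("Caucasian", "East Asian", "other/mixed")


def draw_biometry(spec: CohortSpec,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the biometry table (two eyes per participant), no scans.

    Interocular correlation comes from a shared participant-level axial
    length component plus an eye-level deviation.  Spherical equivalent is
    ``se_from_al_slope · (AL − al_emmetropia) + noise`` split into sphere
    and a small minus-cylinder.  Warns (but proceeds) if the realized myope
    fraction is far from the target in a large cohort — a sign the AL→SE
    mapping and the target are mutually infeasible.
    """
    rng = rng or np.random.default_rng(spec.seed)
    n = spec.n_participants
    rho = spec.interocular_al_correlation
    z_p = rng.normal(size=n)
    z_e = rng.normal(size=(n, 2))
    al = spec.al_mean + spec.al_sd * (math.sqrt(rho) * z_p[:, None]
                                      + math.sqrt(1.0 - rho) * z_e)
    al = np.clip(al, 15.0 + 1e-6, 35.0 - 1e-6)

    # refraction noise is mostly shared between a participant's eyes, as in
    # real cohorts (interocular SE correlation ~0.9)
    se = spec.se_from_al_slope * (al - spec.al_emmetropia) \
        + rng.normal(0.0, spec.se_noise_shared_sd, size=n)[:, None] \
        + rng.normal(0.0, spec.se_noise_eye_sd, size=al.shape)
    cyl = -np.abs(rng.normal(0.0, 0.25, size=al.shape))
    sphere = se - cyl / 2.0
    snr = np.clip(rng.normal(28.0, 4.0, size=al.shape), 5.0, 45.0)
    corneal_radius = rng.normal(7.8, 0.25, size=n)

    sex = rng.choice(["F", "M"], size=n)
    ethnicity = rng.choice(_ETHNICITIES, size=n, p=spec.ethnicity_probs)
    participant_offset = rng.normal(0.0, spec.participant_sd, size=n)
    eye_offset = rng.normal(0.0, spec.eye_sd, size=(n, 2))

    rows = []
    width = len(str(n))
    for i in range(n):
        pid = f"P{i + 1:0{width}d}"
        for e, eye in enumerate(("OD", "OS")):
            se_ie = float(se[i, e])
            rows.append({
                "participant_id": pid,
                "eye": eye,
                "axial_length_mm": float(al[i, e]),
                "corneal_radius_mm": float(corneal_radius[i]),
                "sphere_d": float(sphere[i, e]),
                "cylinder_d": float(cyl[i, e]),
                "snr": float(snr[i, e]),
                "sex": str(sex[i]),
                "ethnicity": str(ethnicity[i]),
                "refractive_group": classify_refractive_group(se_ie),
                "thickness_offset_um": float(
                    participant_offset[i] + eye_offset[i, e]
                    + (spec.sex_effect if sex[i] == "M" else 0.0)),
            })
    df = pd.DataFrame(rows)
    is_myope = df["refractive_group"] == "myope"
    df.loc[is_myope, "thickness_offset_um"] -= spec.myope_thinning
    frac = float(is_myope.mean())
    if n >= 500 and abs(frac - spec.myope_fraction_target) > 0.05:
        warnings.warn(
            f"realized myope fraction {frac:.2f} is more than 5 points from "
            f"the target {spec.myope_fraction_target:.2f}; the AL→SE mapping "
            "may be inconsistent with the target", stacklevel=2)
    return df


def _eye_biometry_from_row(row: pd.Series) -> EyeBiometry:
    return EyeBiometry(participant_id=row["participant_id"], eye=row["eye"],
                       axial_length=row["axial_length_mm"],
                       sphere=row["sphere_d"], cylinder=row["cylinder_d"],
                       corneal_radius=row["corneal_radius_mm"],
                       snr=row["snr"], sex=row["sex"],
                       ethnicity=row["ethnicity"])


def simulate_cohort(spec: CohortSpec, model: PitModel,
                    geometry: ScanGeometry,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[pd.DataFrame, dict[tuple[str, str], ThicknessMap]]:
    """Biometry table plus one simulated scan per eye.

    Identical output for identical seed.  Scan keys are
    ``(participant_id, eye)``.
    """
    rng = rng or np.random.default_rng(spec.seed)
    biometry = draw_biometry(spec, rng)
    scans: dict[tuple[str, str], ThicknessMap] = {}
    for _, row in biometry.iterrows():
        bio = _eye_biometry_from_row(row)
        # fixation jitter: scans are centred on the fovea by the operator,
        # but the pit lands at an arbitrary sub-raster position
        jitter = tuple(np.clip(
            rng.normal(0.0, spec.fixation_jitter_mm, size=2), -0.4, 0.4))
        scans[(bio.participant_id, bio.eye)] = simulate_scan(
            model, geometry, bio, noise_sd=spec.noise_sd, seed=rng,
            fovea_offset_mm=jitter,
            thickness_offset=row["thickness_offset_um"])
    return biometry, scans
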