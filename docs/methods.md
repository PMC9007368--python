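# Methods

## Magnification model

The transverse scale of an OCT raster (mm of retina per pixel) is reported
by the device for a schematic eye of fixed axial length, 24.385 mm for the
Spectralis (`SPECTRALIS_ASSUMED_AL_MM`; 24.46 and 24.00 are documented
alternates for Cirrus and Copernicus and can be set per `ScanGeometry`).
For an eye of measured axial length AL the true scale is

    corrected_scale = default_scale × AL / assumed_AL.

The ratio acts on visual angle and is therefore applied isotropically to
both transverse directions (A-scan pitch and B-scan spacing). Only axial
length enters: corneal-curvature magnification is assumed to be handled
inside the device (the reported "Scaling X" is treated as opaque device
output), and no three-variable schematic-eye formula (lens, anterior
chamber) is used. Axial lengths outside 15–35 mm raise a hard error rather
than passing through: a unit mistake (μm, m) would otherwise silently
corrupt every downstream sector mean.

Correction is purely a *region-placement* change: the corrected ETDRS grid
is built with the corrected scales, then both grids average the same,
unresampled per-A-scan thickness values.

## Thickness extraction and fovea localization

Full retinal thickness is the axial ILM–RPE separation per A-scan,
converted to μm via the axial resolution when surfaces arrive in pixels.
A-scans where the surfaces cross or are missing are flagged invalid and
excluded from sector averages; more than 10% invalid is treated as a failed
segmentation and raises.

The foveal centre is the minimum of a moving-average-smoothed thickness map
(kernel 0.25 mm, configurable — wide enough to suppress per-pixel noise,
narrow enough not to displace a ~0.35 mm pit), searched within 1.5 mm of
the scan centre (the acquisition protocol centres scans on the fovea; a
wider search invites ectopic minima). Ties break toward the scan centre and
the discrete minimum is refined by separable quadratic interpolation —
sub-pixel accuracy matters only for the 0.5 mm central sector, but there it
does. Both grids for an eye share one detected centre.

## ETDRS sectorization conventions

Radius bins are half-open — [0, 0.5), [0.5, 1.5), [1.5, 3.0) mm — and the
±45° diagonals belong to the horizontal (nasal/temporal) quadrants. Pixel
membership is a pixel-centre point-in-region test with no area weighting,
matching per-A-scan extraction and keeping the brute-force test oracle
trivial. Sector means are unweighted means of valid pixels; the sparse
31-row raster is used as-is, with no vertical interpolation. Nasal
orientation defaults to image-right for OD and image-left for OS (the side
toward the optic disc when the image is displayed as the examiner sees the
patient) and is configurable, since export conventions vary. A per-sector
truncation fraction (sector area outside the scanned field, estimated from
the pixel-count deficit) is reported, with a warning above 20%.

## Synthetic retina and scanner

The ground-truth retina is a radial difference-of-Gaussians profile

    T(r) = t_periphery + a_para·exp(−(r−r_peak)²/2σ_para²)
                       − a_pit·exp(−r²/2σ_pit²)

— the simplest smooth surface with a thin fovea, a parafoveal peak and a
gentle peripheral decline. Defaults (t_periphery 290 μm, a_para 50 μm,
r_peak 1.3 mm, σ_para 0.9 mm, a_pit 120 μm, σ_pit 0.35 mm) put sector means
in the plausible 250–340 μm range for young healthy maculae; they are
configuration, not normative values, and no claim is made that they match
any particular cohort's absolute thickness. Optional features: a nasal
parafoveal asymmetry multiplier (smoothly blended across the vertical
midline) and a biological axial-length thinning slope with separate central
and peripheral coefficients (μm per mm of AL above the device default),
zero by default.

The simulated scanner samples this surface at each pixel's *true* position
(device pitch × AL/assumed — the actual field of view), adds i.i.d.
Gaussian measurement noise, and stamps the output with the device-default
scales, reproducing the magnification error exactly as a real instrument
does. Sector means of the continuous model over exact annular-sector
boundaries are available by Gauss–Legendre quadrature in polar coordinates
(96 nodes per axis by default; converged to ≪ 0.01 μm for these smooth
profiles). The same oracle with radial bounds dilated by AL/assumed
predicts what an uncorrected grid measures, so the raw-measurement bias and
its derivative in AL have independent closed-ish-form references.

## Cohort generator

`CohortSpec` emulates a community-based young-adult sample: participant
axial length N(23.6, 0.9²) mm with interocular correlation 0.95 (shared
participant component plus eye-level deviation), spherical equivalent from
a linear AL→SE mapping (−1.5 D/mm around an emmetropic AL of 24.0 mm) plus
refraction noise split into a shared participant component (0.65 D) and an
eye component (0.35 D) — interocular SE correlation ≈ 0.9, myope share
(SE ≤ −0.50 D) ≈ 23–24%, SE spread ≈ 1.55 D. The AL→SE mapping is a crude
emmetropization-failure device whose only purpose is realistic group
structure; it is explicitly non-biological. Thickness offsets: participant
level (12 μm), eye level (4 μm), a sex offset (+5 μm for males), optional
uniform myope thinning for recovery studies. Each scan gets fixation
jitter — a Gaussian fovea-to-raster misalignment (σ 0.10 mm per axis) —
because a pit always perfectly centred on the middle B-scan row is not how
real acquisitions land, and on a 31-row raster that artificial alignment
produces an AL-locked discretization artefact in the central sector that
jitter (like reality) dithers away. Scan SNR is drawn around 28 ± 4, so a
few percent of eyes fail the SNR ≥ 20 gate, exercising the exclusion path.
All randomness flows from one integer seed through one generator.

What the generator does *not* model: speckle, segmentation error, choroid,
axial-length measurement error, pathology, and heavy-tailed anisometropia.
Passing tests therefore demonstrate correctness of the pipeline's geometry
and statistics under controlled conditions, not robustness to real-world
image artefacts.

## Statistical models

All models are linear mixed models fitted by REML (statsmodels `MixedLM`),
with sex and ethnicity (3-level) always included as fixed covariates and
participant as the grouping factor; p-values are Wald tests at two-sided
α = 0.05, Bonferroni-adjusted within each nine-sector family.

- **Correction main effect** — thickness ~ correction + covariates, random
  intercept and a random slope on the correction flag (the within-eye
  repeated factor). The coefficient is the mean corrected − raw difference;
  with a balanced paired design and no noise it equals the arithmetic mean
  of the per-eye differences exactly. If corrected and raw values are
  identical for every eye (all AL at the device default) the difference is
  exactly zero with zero variance and a zero estimate is returned without a
  (singular) fit.
- **AL × correction interaction** — adds AL and AL×correction; the
  interaction coefficient is the per-mm-of-AL change in (corrected − raw).
  Simple AL slopes on the raw and corrected data are fitted separately with
  random intercepts.
- **Refractive-group contrast** — thickness ~ group + covariates per
  correction state, random intercept. Which factor carries the random
  slope is genuinely open; the slope is put on the correction flag because
  that is the repeated factor shared by both eyes, and the group models
  (which contain no correction flag) use intercepts only.

Convergence policy: L-BFGS, 200 iterations; a singular or non-convergent
fit falls back to a random intercept only, then to OLS with
cluster-robust (by participant) standard errors; the model actually used is
recorded on every estimate. Covariates with a single observed level are
dropped from the formula rather than fitted.

## Problem sizes in the test suite

Replicate studies run on the 31-line protocol with the lateral A-scan count
reduced to 128 or 64 (sector means are insensitive to lateral density far
above the sector scale): direction-law sign pattern, 50 replicates of 40
participants; attenuation pattern, 50 replicates of 500 participants;
parameter recovery (AL slope −2.0 μm/mm, myope thinning 3 μm, outer
temporal sector), 50 replicates of 150; type-I control, 200 replicates of
100 with the sector table built directly on the biometry generator (with
all AL at the device default the imaging stage is an exact identity, so
this isolates the statistics stage). Quadrature-vs-pixel-mean agreement is
checked on a dense 512×512 near-isotropic raster at 0.5 μm tolerance.

## Known limitations

- **Binary eye-level contrasts in conditional models.** The myope −
  non-myope contrast from a random-intercept LMM is a precision-weighted
  blend of between-participant information (which carries the full
  magnification bias, ≈ bias slope × group AL gap) and within-participant
  information from myopia-discordant fellow-eye pairs. Under Gaussian
  interocular structure, discordant pairs sit near the SE threshold with
  small interocular AL gaps, so their within-pair contrast is only a
  fraction of the population contrast, and with realistic variance
  components the within information receives most of the weight. The
  estimated raw-data contrast is therefore attenuated relative to the
  population-averaged (e.g. cluster-robust OLS) value — a property of the
  estimand, not a bug; it is strongest exactly when the group difference is
  pure magnification with no biological component. Real cohorts, where
  biological AL-thinning adds to the raw contrast, show larger and more
  often significant raw contrasts than magnification-only simulations do.
- The fovea detector assumes a pit-shaped map within 1.5 mm of the scan
  centre; gross decentration or foveal pathology is out of scope.
- Sector means on the 31-row raster carry discretization noise of a few
  tenths of a μm (central sector worst); the quadrature oracle quantifies
  it but the pipeline does not interpolate it away, mirroring per-A-scan
  clinical extraction.
- No E2E/proprietary parsing: inputs are pre-segmented surfaces or
  thickness maps plus a geometry sidecar (a documented extension point).
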