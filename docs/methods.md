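# Methods

This note documents the models behind `besselao`, the choices that were
genuinely open, and what the synthetic benchmarks do and do not establish.

## Optical model

All pupil-plane quantities live on a square grid in numerical-aperture (NA)
units. The objective disk has diameter `grid_n / 2` pixels (the grid extends
to twice the objective NA), which keeps the focal field Nyquist-sampled
before the configured zero-padding (`pupil_oversampling`, default 2x) is
applied. Propagation between the pupil and its focal conjugate is a unitary
centered FFT; pupil and focal pitches obey `dx = lambda / (N_pad * dna)`.

**Scalar Debye engine.** The focal field at defocus `z` is the transform of
the pupil multiplied by `exp(i k0 z sqrt(n^2 - NA^2))` with sine-condition
apodization `sqrt(cos theta)`. One-photon intensity is `|U|^2`; the
two-photon excitation signal is its square. This engine produces every 2-D/
3-D field in the package: PSF volumes, segment-illumination bead images,
pattern validation, phantom imaging.

**Vectorial axial profiles.** For *absolute* axial widths the scalar model
carries a small but consequential bias: exact quadrature gives a two-photon
axial FWHM of 1.191 µm for the full 1.05-NA pupil at 940 nm in water,
whereas the on-axis Richards–Wolf integral (only the `I0` term survives on
axis for linear polarization) gives 1.177 µm; the annular focus moves from
44.3 to 44.4 µm. Because the discrepancy is pure model bias — it cancels in
every ratio the package reports — the volumetric engine stays scalar, and
`vectorial_axial_profile` is used wherever an axial FWHM is quoted as an
absolute number.

**Zernike conventions.** Un-normalized Born & Wolf circle polynomials
(`R_n^{|m|}(1) = 1`, defocus `2 rho^2 - 1`; `cos`/`sin` azimuthal factors for
`m >= 0` / `m < 0`), with `rho` scaled to the objective NA. A coefficient of
"1 wave" means the peak polynomial value contributes one wavelength of path
difference — the common SLM-control convention; peak-to-valley and RMS
readings of the same surface differ by mode-dependent factors (e.g. PV = 2
and RMS = 1/sqrt(6) for astigmatism at unit coefficient), so this choice
must be kept in mind when comparing degradation magnitudes across sources.
The "first 55 modes" are radial orders 0–9 ordered by `n` then `m`
ascending. Phases are stored wrapped to `(-pi, pi]`; 8-bit SLM export maps
`[0, 2 pi)` linearly onto 0–255.

## The focal-plane corrective pattern

The pipeline is fixed: truncate the measured corrective wavefront to the
pupil disk → least-squares fit of the first 55 modes (segmented sensing
output has discontinuous gradients; the modal fit is the smoothing step, and
a residual RMS above 0.15 waves is recorded as a warning, not an error) →
remove tip, tilt and defocus (tip/tilt would displace the annular
illumination from the physical mask; defocus would skew the axial profile of
the Bessel focus) → impose the annular amplitude → Fourier-propagate → keep
only the phase.

Discarding the focal amplitude is the method's defining approximation.
`validate_focal_pattern` quantifies it by inverse-propagating the phase-only
pattern under uniform illumination and reporting (a) the fraction of pupil
energy landing in the annular band, normalized by the same quantity for the
zero-aberration pattern, and (b) the circular correlation
`|<exp(i(phi_rec - phi_expected))>|` (amplitude²-weighted, offset-invariant)
inside the strict annulus. The strict band matters: the first diffraction
sidelobes just outside the ring carry π-flipped phase and would wreck the
statistic while being irrelevant to what the mask transmits. Default
acceptance thresholds — containment ≥ 0.8 of ideal, correlation ≥ 0.9 — are
configurable; smooth aberrations up to 1.5 waves RMS validate at ≈ 1.0 and
0.94–0.98 respectively.

Two masking operators exist deliberately. `apply_annulus` is a strict mask
(binary indicator, values inside untouched — idempotent), used wherever a
physical aperture clips a beam. `annulus_field`/`annulus_amplitude` build
anti-aliased rings, used wherever the ring itself is synthesized: the
hardware ring is only ~3 pixels wide at the default grid and a binary
indicator would misstate its area by ~10%.

**Through-system simulation.** `simulate_bessel_peak` models the chain
SLM1 → mask → (optional displaced phase screen) → pupil → objective. The
screen is a thin phase mask placed `d` mm from the pupil conjugate in the
collimated relay space (paraxial Fresnel steps); pupil-plane AO applies its
phase *after* the screen and cannot undo the phase-to-amplitude conversion
accumulated over `d`, while the focal-plane pattern's correction travels
with the beam and cancels the screen where it acts — the package's
restatement of why pupil AO underperforms for Bessel foci. Because the
uniform-illumination idealization lets different patterns push different
total power through the mask, the clipped pupil field is renormalized to
fixed delivered power; peak ratios therefore measure focus quality.
Corrected-over-ideal ratios slightly above 1 are real in this metric: the
ideal phase-only pattern has its own synthesis imperfection.

## Aberration-mode sensitivity

Two distinct questions get two distinct defaults.

1. *Which modes does a Bessel focus feel?* (`mode_sensitivity_scan`)
   Aberrations are placed on the full pupil, as sample aberrations
   physically are, and the peak is the global two-photon maximum with an
   axial search wide enough to absorb refocusing (±2 axial FWHM, extended
   by the paraxial defocus shift `~4 n lambda a / NA^2` for m = 0 modes).
   For an ideal thin annulus every mode with `|m| <= 1` is locally piston
   (m = 0) or tilt (|m| = 1) on the ring and costs ≤ 5% signal even at a
   full wave, while `|m| >= 2` modes corrugate the ring phase and always
   lose signal — the azimuthal-index law that makes Bessel foci robust to
   spherical aberration and coma but vulnerable to astigmatism and trefoil.

2. *Which beam suffers more?* (`beam_sensitivity_comparison`) A cross-beam
   comparison is only meaningful when "1 wave" denotes the same wavefront
   deviation over the zone each beam illuminates, so the Zernike unit disk
   is scaled to each beam's own aperture (full NA vs ring NA). At one wave
   both beams' *global* maxima sit at side-lobe level and the comparison
   degenerates into comparing stray lobes; the informative statistic is the
   central-lobe ("core") peak — the maximum within one unaberrated
   core radius of the beam centroid, centroid-tracked so a tilted-but-intact
   core still counts. Under this metric astigmatism and trefoil collapse the
   ring's `J0`-interference core (ratios ~1e-3) far below the Gaussian's
   remaining core (~1e-2), while coma and spherical leave the ring near
   unity: the asymmetry that motivates correcting Bessel foci at all.

Regression values for these ratios are frozen from this implementation's own
converged runs; they are properties of the stated conventions, not imported
numbers.

## Pupil-segmentation sensing

The pupil is tiled 5 × 5; corner tiles keep ≥ 25% disk overlap or are
dropped (21 informative tiles remain), and tiles are weighted by inside
area. Each tile's beamlet images a bead (projected-sphere kernel, default
2 µm); displacements are estimated by upsampled cross-correlation of each
tile image against its *zero-aberration template* — the calibration images
an instrument records once without a sample. Registering instead against
the aberrated full-pupil image (also available, `method="xcorr"`) fails at
wave-level aberrations because a smooth beamlet blob cannot be registered
to a speckled reference; an intensity-centroid option (`method="com"`)
exists for degraded data.

Shift-to-gradient calibration follows from the Fourier shift theorem: a
tilt of `g` waves per NA unit displaces the focus by `g * lambda` µm. The
reconstructor converts shifts to per-tile mean gradients, removes the
weighted uniform component (tip/tilt is declared null space and must not
leak into higher modes), and solves a weighted least-squares system against
the tile-averaged analytic mode gradients — modal integration, since the
downstream consumer is modal anyway and 25 tiles cannot support meaningful
zonal reconstruction. Piston, tip and tilt are returned as zero. Default
mode count is 21 (radial orders ≤ 5); an under-determined request is
reduced with a warning.

A single measure-and-correct pass leaves a registration-limited residual of
~0.05–0.15 waves at wave-level aberrations (beamlets are distorted by the
very aberration being measured). `closed_loop_bessel_recovery` therefore
iterates the cycle (default 2 passes) with the running correction applied
during re-measurement, as indirect sensing is operated in practice; the
second pass measures a nearly flat wavefront and removes the residual. At a
512-pixel grid (the hardware ring needs ≥ ~6 pixels of radial sampling for
faithful pattern synthesis) the loop recovers 0.90–1.26 of the unaberrated
two-photon peak across 20 random smooth aberrations at 1 wave RMS.

**Random smooth aberrations** are Zernike sums over radial orders 2–4 with
coefficients ~ N(0, 1/n²), rescaled to a requested disk RMS — low-order
dominated, as cranial-window and index-mismatch aberrations are.

## Imaging simulator

Phantoms are rendered at ≤ 0.2-µm voxels with anti-aliased spheres: beads
(0.1–2 µm), or a smooth dendrite polyline with spherical spines
(0.5–1.5 µm diameter, 1–2 µm stems) and a ground-truth catalog. Gaussian
stacks are full 3-D convolutions with the two-photon PSF; a Bessel frame is
the central plane of the same convolution with the axially extended Bessel
PSF — one 2-D sweep records the whole axial extent, which is the volumetric-
rate argument for Bessel scanning. Poisson noise is parameterized by the
expected photon count at the brightest pixel. Richardson–Lucy deconvolution
uses circulant FFT convolution so that every iteration conserves flux
exactly; it is initialized from the blurred data. A spine counts as
"resolvable" when a local maximum within 0.5 µm of its catalog position
exceeds the image background median by 2x (both configurable) — a
programmatic stand-in for manual spine counting.

## Functional statistics

Per-trial ΔF/F₀ uses that epoch's pre-stimulus blank as F₀ (robust to slow
drift; ROIs with any non-positive baseline are excluded). Evoked response R
is the mean ΔF/F₀ over the grating epoch; transients are R > 20% for
calcium and R > 10% for glutamate by default (5% is the documented
alternative threshold). Orientation selectivity is a one-way ANOVA across
the 12 directions at p < 0.05, with degenerate zero-variance inputs mapped
to p = 1 (flat) or p = 0 (tuned). Only selective ROIs are fitted with the
bimodal Gaussian tuning curve; the fit multi-starts θ_pref at all 12
stimulus directions, ties resolved toward smaller σ, and the taller peak
defines θ_pref. The gOSI takes the modulus of the 2θ-phasor mean (the
printed index is a nonnegative scalar in [0, 1]; without the modulus it is
complex), flooring negative mean responses at zero first. Dominant
orientations come from a wrapped-Gaussian fit to the θ_pref histogram on
[0°, 180°); a peak is reported only if its amplitude exceeds 3x the
counting-noise scale `sqrt(mean bin count)` *and* its FWHM is below 120°
(wider fits on a 180° domain are flat histograms in disguise).

The session generator produces raw-fluorescence traces: baseline × (1 +
amplitude × indicator kernel) per epoch, with saturating-exponential rise
during the grating and exponential decay after (defaults 0.25 s / 1.0 s for
calcium; ~0.05 s / 0.15 s emulates glutamate sensors), tuned amplitudes from
the bimodal Gaussian, optional per-trial jitter, and additive Gaussian read
noise. Trial schedules default to the two acquisition modes: 2/4/2 s at
3.3 Hz (Gaussian scanning) and 4/6/2 s at 1.5 Hz (Bessel scanning), 12
directions × 10 trials, seeded pseudorandom order.

## What the synthetic benchmarks do and do not show

The generator-based properties (closed-loop recovery, responsive-fraction
recovery, θ_pref recovery, ANOVA calibration, SNR-monotonicity of transient
detection and gOSI) validate the *analysis chain and the optical pipeline
against known ground truth*. They share the forward model with the methods
under test in two places that real data would not: the sensing simulator and
reconstructor share one shift calibration, and tuned responses are generated
from the same functional form that is fitted. They therefore establish
correctness and calibration, not in-vivo performance; published in-vivo
quantities that depend on unreleased raw data (spine counts, gOSI medians,
apical–basal orientation shifts) are deliberately out of scope.

One published number is not reproduced by the faithful forward model: the
2-µm bead's axial FWHM. A 2.0-µm uniform sphere convolved with *any* kernel
near the also-published 1.08-µm PSF width has a through-center FWHM of
~2.1–2.2 µm; the package's converged value is 2.15 µm against a published
2.6 µm. The excess in the measurement plausibly includes refraction inside
the high-index bead and finite z-step sampling, neither of which belongs in
a linear convolution model; the two published numbers are mutually
inconsistent within one. The simulation is reported as computed.

## Problem sizes and numerics

Default grid 256 px (disk diameter 128 px), 2x padding; 512 px where the
thin ring's radial sampling matters (closed loop, convergence checks);
1024+ px or 1-D quadrature for absolute FWHM numbers. Axial searches use
31–41 planes with parabolic peak refinement. FWHM is always linear
interpolation of the half-maximum crossings around the global peak.
Discrete Zernike orthogonality on the 256-px grid holds to ~1–2 × 10⁻³
relative inner product (edge-pixel quadrature is the limit); fits are plain
least squares and are exact for in-span inputs regardless.
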