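"""Focal-plane adaptive optics for Bessel foci — the core algorithm.

A Bessel focus is generated by annular illumination of the objective pupil.
Correcting its aberrations with a phase-only SLM at the *pupil* plane fails
when the aberration arises away from that plane, because propagation turns
phase errors into amplitude errors on the thin annulus, which no phase mask
can undo.  The remedy implemented here: compute a phase-only pattern for the
SLM conjugate to the *focal* plane whose Fourier transform reproduces, at
the pupil, both the annular amplitude and the corrective phase.

Pipeline (``compute_focal_correction``):

1. truncate the measured corrective wavefront to the pupil disk;
2. fit the first 55 Zernike modes (a smooth surrogate of the segmented,
   gradient-discontinuous measurement);
3. remove tip, tilt and defocus — tip/tilt would walk the annular
   illumination off the physical mask, defocus would skew the axial profile
   of the Bessel focus;
4. impose the annular amplitude on the rebuilt smooth wavefront;
5. Fourier-propagate to the focal plane and keep only the phase.

``validate_focal_pattern`` closes the loop: inverse-propagate the phase-only
pattern under a uniform amplitude assumption and check that the annular
amplitude and the corrective phase reappear at the pupil.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import OpticalConfig
from .pupil import (
    FocalField,
    FocalPattern,
    PupilField,
    disk_amplitude,
    make_pupil_grid,
    propagate,
    wrap_phase,
)
from .zernike import (
    DEFOCUS,
    TILT,
    TIP,
    ModeIndex,
    ZernikeCoefficients,
    fit_zernike,
)

DEFAULT_REMOVED_MODES: tuple[ModeIndex, ...] = (TILT, TIP, DEFOCUS)


# ---------------------------------------------------------------------------
# Annular mask geometry


@dataclass(frozen=True)
class AnnularMaskSpec:
    """Annular amplitude mask mapped onto the objective back pupil.

    ``na_inner``/``na_outer`` are the numerical apertures subtended at the
    objective by the mask's inner/outer radii after relay magnification.
    """

    inner_diameter_mm: float
    outer_diameter_mm: float
    magnification_to_pupil: float
    na_inner: float
    na_outer: float

    def __post_init__(self) -> None:
        if not (0 < self.inner_diameter_mm < self.outer_diameter_mm):
            raise ValueError("need 0 < inner diameter < outer diameter")
        if not (0 < self.na_inner < self.na_outer):
            raise ValueError("need 0 < na_inner < na_outer")

    @classmethod
    def from_hardware(
        cls,
        config: OpticalConfig,
        inner_diameter_mm: float = 1.015,
        outer_diameter_mm: float = 1.2,
    ) -> "AnnularMaskSpec":
        """Derive the pupil annulus from the physical mask and relay chain."""
        na_inner, na_outer = derive_annulus_na(inner_diameter_mm, outer_diameter_mm, config)
        return cls(
            inner_diameter_mm=inner_diameter_mm,
            outer_diameter_mm=outer_diameter_mm,
            magnification_to_pupil=config.relay_magnification,
            na_inner=na_inner,
            na_outer=na_outer,
        )

    @classmethod
    def from_na(cls, na_inner: float, na_outer: float, config: OpticalConfig | None = None) -> "AnnularMaskSpec":
        """Nominal-NA parameterization (e.g. a 0.4-NA annulus), bypassing the
        physical mask geometry."""
        if config is not None and na_outer > config.na_objective:
            raise ValueError("annulus exceeds the objective NA")
        f_obj = config.objective_focal_mm if config else 8.0
        return cls(
            inner_diameter_mm=2 * na_inner * f_obj,
            outer_diameter_mm=2 * na_outer * f_obj,
            magnification_to_pupil=1.0,
            na_inner=na_inner,
            na_outer=na_outer,
        )


def derive_annulus_na(
    inner_diameter_mm: float,
    outer_diameter_mm: float,
    config: OpticalConfig,
) -> tuple[float, float]:
    """NA of the mask's inner/outer radii at the objective pupil.

    The mask radius is magnified by the relay chain onto the back pupil of
    radius ``na_objective * f_obj``; the NA subtended scales linearly with
    pupil radius.
    """
    mag = config.relay_magnification
    pupil_radius_mm = config.pupil_radius_mm
    na = tuple(
        config.na_objective * (d / 2 * mag) / pupil_radius_mm
        for d in (inner_diameter_mm, outer_diameter_mm)
    )
    if na[1] > config.na_objective:
        raise ValueError(
            f"annulus outer NA {na[1]:.3f} exceeds the objective NA {config.na_objective}"
        )
    return na


def annulus_amplitude(pupil: PupilField, mask: AnnularMaskSpec) -> np.ndarray:
    """Anti-aliased annular transmission map on a pupil grid (used when the
    ring itself is being synthesized, so that thin rings keep their area)."""
    rho = pupil.na_radius()
    outer = disk_amplitude(rho, mask.na_outer, pupil.na_per_px)
    inner = disk_amplitude(rho, mask.na_inner, pupil.na_per_px)
    return outer - inner


def apply_annulus(pupil: PupilField, mask: AnnularMaskSpec) -> PupilField:
    """Zero the amplitude outside [na_inner, na_outer]; values inside (phase
    and amplitude) are untouched, so applying the mask twice equals once."""
    rho = pupil.na_radius()
    band = (rho >= mask.na_inner) & (rho <= mask.na_outer)
    if not band.any():
        raise ValueError("annulus is empty after discretization; increase grid_n")
    return pupil.copy_with(pupil.values * band)


def annulus_field(mask: AnnularMaskSpec, config: OpticalConfig) -> PupilField:
    """Unit-amplitude annular pupil field with anti-aliased edges."""
    pupil = make_pupil_grid(config)
    band = annulus_amplitude(pupil, mask)
    if not np.any(band > 0.25):
        raise ValueError("annulus is empty after discretization; increase grid_n")
    return pupil.copy_with(band.astype(complex))


# ---------------------------------------------------------------------------
# Bessel pattern for the focal-plane SLM


def binary_axicon(period_px: float, grid_n: int) -> np.ndarray:
    """Concentric binary phase grating (alternating 0 / pi rings).

    This is the classic SLM pattern that diffracts most of the light into
    the +/-1 orders forming a ring at the mask plane; ``period_px`` is the
    radial period in pixels per cycle (each ring is half a period wide).
    """
    if period_px < 4:
        raise ValueError("period under-sampled: need period_px >= 4")
    ax = np.arange(grid_n) - grid_n // 2
    r = np.hypot(ax[None, :], ax[:, None])
    ring = np.floor(2 * r / period_px).astype(int)
    return np.where(ring % 2 == 1, np.pi, 0.0)


def ideal_bessel_pattern(mask: AnnularMaskSpec, config: OpticalConfig) -> FocalPattern:
    """Focal-plane phase producing the unaberrated annulus (zero-correction
    limit of :func:`compute_focal_correction`)."""
    return compute_focal_correction(None, mask, config).pattern


# ---------------------------------------------------------------------------
# Correction pipeline


@dataclass
class CorrectionBundle:
    """Every stage of the focal-pattern computation, for auditability."""

    input_wavefront: np.ndarray | None
    fitted: ZernikeCoefficients
    edited: ZernikeCoefficients
    smooth_wavefront: np.ndarray
    fit_residual_rms: float
    masked_pupil: PupilField
    pattern: FocalPattern
    validation: dict = field(default_factory=dict)


def compute_focal_correction(
    pupil_wavefront: np.ndarray | None,
    mask: AnnularMaskSpec,
    config: OpticalConfig,
    *,
    n_modes: int = 55,
    removed_modes: tuple[ModeIndex, ...] = DEFAULT_REMOVED_MODES,
    residual_warn_rms: float = 0.15,
    validate: bool = True,
) -> CorrectionBundle:
    """Compute the phase-only focal-plane corrective pattern.

    Parameters
    ----------
    pupil_wavefront:
        Corrective wavefront in waves on the pupil grid (``None`` or zeros
        give the ideal Bessel-generating pattern).
    residual_warn_rms:
        Zernike-fit residual RMS (waves) above which a warning is recorded;
        segmented wavefront-sensing outputs are flat-tile surfaces with
        discontinuous gradients, so some residual is expected.
    """
    disk = make_pupil_grid(config)
    if pupil_wavefront is None:
        pupil_wavefront = np.zeros((config.grid_n, config.grid_n))
    pupil_wavefront = np.asarray(pupil_wavefront, dtype=float)
    if pupil_wavefront.shape != disk.values.shape:
        raise ValueError("wavefront shape does not match the pupil grid")

    # 1-2: truncate to the disk and fit the smooth modal surrogate
    fitted, residual = fit_zernike(pupil_wavefront, disk, n_modes=n_modes)
    res_rms = float(np.sqrt(np.mean(residual[disk.disk_mask()] ** 2)))
    warnings_list = []
    if res_rms > residual_warn_rms:
        msg = f"Zernike fit residual RMS {res_rms:.3f} waves exceeds {residual_warn_rms}"
        warnings_list.append(msg)
        warnings.warn(msg, stacklevel=2)

    # 3: drop tip/tilt (annulus centering) and defocus (axial-profile skew)
    edited = fitted.remove(removed_modes)
    smooth = edited.surface(disk)

    # 4: annular amplitude (anti-aliased ring) carrying the corrective phase
    band = annulus_amplitude(disk, mask)
    if not np.any(band > 0.25):
        raise ValueError("annulus is empty after discretization; increase grid_n")
    masked = disk.copy_with(band * np.exp(2j * np.pi * smooth))

    # 5: propagate to the focal plane; the SLM keeps only the phase
    focal = propagate(masked, "pupil_to_focal", config)
    pattern = FocalPattern(phase=np.angle(focal.values), pitch_um=focal.pitch_um)

    bundle = CorrectionBundle(
        input_wavefront=pupil_wavefront,
        fitted=fitted,
        edited=edited,
        smooth_wavefront=smooth,
        fit_residual_rms=res_rms,
        masked_pupil=masked,
        pattern=pattern,
    )
    if warnings_list:
        bundle.validation["warnings"] = warnings_list
    if validate:
        bundle.validation.update(validate_focal_pattern(pattern, mask, smooth, config))
    return bundle


def back_propagated_pupil(pattern: FocalPattern, config: OpticalConfig) -> PupilField:
    """Inverse transform of exp(i * pattern) under uniform amplitude."""
    focal = FocalField(
        values=np.exp(1j * pattern.phase),
        pitch_um=pattern.pitch_um,
        wavelength_um=config.wavelength_um,
    )
    return propagate(focal, "focal_to_pupil", config)


def validate_focal_pattern(
    pattern: FocalPattern,
    mask: AnnularMaskSpec,
    expected_wavefront: np.ndarray | None,
    config: OpticalConfig,
) -> dict:
    """Numerically validate a focal-plane pattern by inverse propagation.

    Back-propagates the phase-only pattern with uniform amplitude and
    reports:

    * ``containment`` — fraction of pupil-plane energy landing inside the
      annular band (slightly dilated to absorb edge diffraction);
    * ``containment_ideal`` / ``containment_ratio`` — same for the
      zero-correction pattern, and their ratio;
    * ``phase_correlation`` — circular correlation ``|<exp(i dphi)>|``
      (amplitude-squared weighted, offset-invariant) between the recovered
      and expected phase inside the annulus;
    * ``centroid_offset_px`` — centroid of back-propagated energy relative
      to the grid center (tip/tilt removal should keep this < 1 px).
    """
    back = back_propagated_pupil(pattern, config)
    report = _containment_and_phase(back, mask, expected_wavefront, config)

    ideal_focal = propagate(annulus_field(mask, config), "pupil_to_focal", config)
    ideal_pattern = FocalPattern(phase=np.angle(ideal_focal.values), pitch_um=ideal_focal.pitch_um)
    ideal_back = back_propagated_pupil(ideal_pattern, config)
    ideal = _containment_and_phase(ideal_back, mask, None, config)
    report["containment_ideal"] = ideal["containment"]
    report["containment_ratio"] = (
        report["containment"] / ideal["containment"] if ideal["containment"] > 0 else np.nan
    )
    return report


def _containment_and_phase(
    back: PupilField,
    mask: AnnularMaskSpec,
    expected_wavefront: np.ndarray | None,
    config: OpticalConfig,
) -> dict:
    rho = back.na_radius()
    pad_na = 2 * back.na_per_px
    # dilated band for energy bookkeeping (absorbs edge diffraction) ...
    band = (rho >= mask.na_inner - pad_na) & (rho <= mask.na_outer + pad_na)
    # ... strict band for phase comparison: the first diffraction sidelobes
    # just outside the ring carry pi-flipped phase and must not vote
    band_strict = (rho >= mask.na_inner) & (rho <= mask.na_outer)
    inten = np.abs(back.values) ** 2
    total = inten.sum()
    containment = float(inten[band].sum() / total) if total > 0 else np.nan

    # energy centroid relative to grid center, in pixels
    n = back.n
    idx = np.arange(n) - n // 2
    cy = float((inten.sum(axis=1) @ idx) / total)
    cx = float((inten.sum(axis=0) @ idx) / total)

    report = {
        "containment": containment,
        "centroid_offset_px": float(np.hypot(cx, cy)),
    }
    if expected_wavefront is not None:
        exp_w = np.asarray(expected_wavefront, dtype=float)
        # compare on the central grid_n window where the expectation lives
        lo = n // 2 - exp_w.shape[0] // 2
        sl = slice(lo, lo + exp_w.shape[0])
        rec = back.values[sl, sl]
        band_c = band_strict[sl, sl]
        dphi = np.angle(rec) - 2 * np.pi * exp_w
        w = np.abs(rec) ** 2 * band_c
        if w.sum() > 0:
            corr = np.abs(np.sum(w * np.exp(1j * dphi)) / w.sum())
        else:
            corr = np.nan
        report["phase_correlation"] = float(corr)
    return report


# ---------------------------------------------------------------------------
# Through-system simulation: pupil AO vs focal AO


def fresnel_propagate(values: np.ndarray, distance_mm: float, config: OpticalConfig) -> np.ndarray:
    """Paraxial free-space step in the collimated space around the pupil.

    Pupil-grid pixels map to physical pitch ``dna * f_obj`` mm; the transfer
    function is ``exp(-i pi lambda d (fx^2 + fy^2))``.  Used to place thin
    aberrating phase screens at planes displaced from the pupil conjugate.
    """
    if distance_mm == 0:
        return values
    n = values.shape[0]
    dx_mm = config.na_per_px * config.objective_focal_mm
    f = np.fft.fftfreq(n, d=dx_mm)
    fx2 = f[None, :] ** 2 + f[:, None] ** 2
    lam_mm = config.wavelength_um * 1e-3
    H = np.exp(-1j * np.pi * lam_mm * distance_mm * fx2)
    return np.fft.ifft2(np.fft.fft2(values) * H)


def sense_pupil_phase(
    aberration_waves: np.ndarray,
    config: OpticalConfig,
    *,
    screen_displacement_mm: float = 0.0,
    n_modes: int = 55,
) -> np.ndarray:
    """Phase (waves) a full-pupil beam accumulates at the pupil plane from a
    thin screen at ``screen_displacement_mm`` upstream, fitted smooth.

    This is the idealized stand-in for a pupil-plane wavefront measurement
    made with the Gaussian beam: it sees only the phase of the complex
    distortion arriving at the pupil.
    """
    disk = make_pupil_grid(config)
    if screen_displacement_mm == 0.0:
        measured = np.asarray(aberration_waves, dtype=float)
    else:
        from skimage.restoration import unwrap_phase

        u = fresnel_propagate(disk.values, -screen_displacement_mm, config)
        u = u * np.exp(2j * np.pi * aberration_waves)
        u = fresnel_propagate(u, screen_displacement_mm, config)
        # the arriving phase exceeds half a wave for typical aberrations, so
        # it must be unwrapped before a polynomial fit makes sense
        wrapped = np.ma.masked_array(np.angle(u), mask=~disk.disk_mask())
        measured = np.asarray(unwrap_phase(wrapped)) / (2 * np.pi)
    coeffs, _ = fit_zernike(measured, disk, n_modes=n_modes)
    return coeffs.surface(disk)


def simulate_bessel_peak(
    config: OpticalConfig,
    mask: AnnularMaskSpec,
    aberration_waves: np.ndarray | None = None,
    *,
    correction: str = "none",
    corrective_wavefront: np.ndarray | None = None,
    screen_displacement_mm: float = 0.0,
    z_search_um: float | None = None,
    n_z: int = 41,
    normalize_throughput: bool = True,
) -> float:
    """Two-photon peak of the Bessel focus through the full excitation chain.

    The sample/system aberration is a thin phase screen either at the pupil
    plane or displaced ``screen_displacement_mm`` upstream of it (in the
    collimated relay space).  Corrections:

    * ``"none"`` — bare annulus from the ideal focal pattern;
    * ``"pupil"`` — phase-only conjugate correction applied *at the pupil*,
      i.e. after the screen: it cannot undo the amplitude ripple a displaced
      screen has already imprinted on the thin annulus;
    * ``"focal"`` — the corrective phase is embedded in the annulus by the
      focal-plane pattern, so it travels with the beam and cancels the
      screen where the distortion physically arises.

    ``corrective_wavefront`` defaults to the sensed smooth phase (sign
    flipped); pass one explicitly to model an imperfect measurement.
    The returned value is an absolute two-photon peak (compare against a
    zero-aberration run for a recovery ratio).
    """
    from .psf import _peak_over_z, estimate_axial_fwhm_scale

    if aberration_waves is None:
        aberration_waves = np.zeros((config.grid_n, config.grid_n))
    aberration_waves = np.asarray(aberration_waves, dtype=float)

    if correction in ("none", "pupil"):
        pattern = ideal_bessel_pattern(mask, config)
        corr_pupil = None
        if correction == "pupil":
            if corrective_wavefront is None:
                corrective_wavefront = -sense_pupil_phase(
                    aberration_waves, config, screen_displacement_mm=screen_displacement_mm
                )
            corr_pupil = np.exp(2j * np.pi * corrective_wavefront)
    elif correction == "focal":
        if corrective_wavefront is None:
            corrective_wavefront = -sense_pupil_phase(
                aberration_waves, config, screen_displacement_mm=screen_displacement_mm
            )
        pattern = compute_focal_correction(
            corrective_wavefront, mask, config, validate=False
        ).pattern
        corr_pupil = None
    else:
        raise ValueError("correction must be 'none', 'pupil' or 'focal'")

    # SLM1 -> (mask plane) -> screen -> pupil
    from .pupil import _crop_center

    incoming = back_propagated_pupil(pattern, config)
    # anti-aliased mask transmission: the thin physical ring is only a few
    # pixels wide, so a binary clip would misrepresent its area
    clipped = incoming.masked().copy_with(
        incoming.masked().values * annulus_amplitude(incoming, mask)
    )
    # the annulus lives well inside the central grid_n window; crop for speed
    clipped = clipped.copy_with(_crop_center(clipped.values, config.grid_n))
    if normalize_throughput:
        # The uniform-amplitude idealization of the SLM illumination lets
        # different patterns send different total power through the mask;
        # fixing the delivered power isolates focus quality.
        clipped = clipped.copy_with(clipped.values / np.sqrt(clipped.energy))
    u = clipped.values
    if screen_displacement_mm != 0.0:
        u = fresnel_propagate(u, -screen_displacement_mm, config)
        u = u * np.exp(2j * np.pi * _pad_like(aberration_waves, u.shape[0]))
        u = fresnel_propagate(u, screen_displacement_mm, config)
    else:
        u = u * np.exp(2j * np.pi * _pad_like(aberration_waves, u.shape[0]))
    if corr_pupil is not None:
        u = u * _pad_like_complex(corr_pupil, u.shape[0])

    pupil = clipped.copy_with(u)
    if z_search_um is None:
        z_search_um = 1.5 * (estimate_axial_fwhm_scale(annulus_field(mask, config), config) or 50.0)
    return _peak_over_z(pupil, config, z_search_um, n_z)


def random_smooth_aberration(
    config: OpticalConfig,
    rms_waves: float = 1.0,
    *,
    n_max: int = 4,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Random smooth wavefront: Zernike modes 2 <= n <= n_max (piston, tip
    and tilt excluded), coefficients ~ N(0, 1/n^2), scaled to the requested
    RMS over the pupil disk.  Stands in for smooth sample-induced
    aberrations."""
    from .zernike import wavefront_rms, zernike_modes

    rng = np.random.default_rng(rng)
    disk = make_pupil_grid(config)
    modes = [mode for mode in zernike_modes(n_max) if mode[0] >= 2]
    coeffs = ZernikeCoefficients({mode: rng.normal(0.0, 1.0 / mode[0] ** 2) for mode in modes})
    surf = coeffs.surface(disk)
    rms = wavefront_rms(surf, disk)
    return surf * (rms_waves / rms) if rms > 0 else surf


def closed_loop_bessel_recovery(
    aberration_waves: np.ndarray,
    config: OpticalConfig,
    mask: AnnularMaskSpec,
    *,
    bead_diameter_um: float = 2.0,
    photon_budget: float | None = None,
    n_modes: int = 21,
    iterations: int = 2,
    rng: np.random.Generator | int | None = None,
    reference_peak: float | None = None,
    compute_uncorrected: bool = True,
    n_z: int = 41,
) -> dict:
    """Full AO loop: sense the aberration by pupil segmentation, compute the
    focal-plane corrective pattern, and report the recovered fraction of the
    unaberrated Bessel two-photon peak.

    ``iterations`` repeats the measure-and-correct cycle with the running
    correction applied during re-measurement, as indirect wavefront sensing
    is operated in practice: a single pass registers beamlets distorted by
    the full aberration and leaves a registration-limited residual of
    ~0.05-0.15 waves at wave-level aberrations, which a second pass (now
    measuring a nearly flat wavefront) removes.

    Returns a dict with ``recovery`` (corrected / unaberrated peak),
    ``uncorrected`` (aberrated / unaberrated), and the reconstructed
    corrective wavefront.
    """
    from .sensing import sense_and_reconstruct

    rng = np.random.default_rng(rng)
    recon = np.zeros_like(np.asarray(aberration_waves, dtype=float))
    coeffs = None
    for _ in range(max(1, iterations)):
        step, step_coeffs = sense_and_reconstruct(
            aberration_waves - recon,
            config,
            bead_diameter_um=bead_diameter_um,
            photon_budget=photon_budget,
            n_modes=n_modes,
            rng=rng,
        )
        recon = recon + step
        coeffs = step_coeffs if coeffs is None else ZernikeCoefficients(
            {k: coeffs[k] + step_coeffs[k] for k in set(coeffs.amplitudes) | set(step_coeffs.amplitudes)}
        )
    ref = reference_peak if reference_peak is not None else simulate_bessel_peak(config, mask, n_z=n_z)
    corr = simulate_bessel_peak(
        config, mask, aberration_waves, correction="focal", corrective_wavefront=-recon, n_z=n_z
    )
    out = {
        "recovery": corr / ref,
        "corrective_wavefront": -recon,
        "coefficients": coeffs,
    }
    if compute_uncorrected:
        out["uncorrected"] = simulate_bessel_peak(config, mask, aberration_waves, n_z=n_z) / ref
    return out


def _pad_like(a: np.ndarray, n: int) -> np.ndarray:
    if a.shape[0] == n:
        return a
    out = np.zeros((n, n), dtype=a.dtype)
    lo = n // 2 - a.shape[0] // 2
    out[lo : lo + a.shape[0], lo : lo + a.shape[0]] = a
    return out


def _pad_like_complex(a: np.ndarray, n: int) -> np.ndarray:
    if a.shape[0] == n:
        return a
    out = np.ones((n, n), dtype=complex)
    lo = n // 2 - a.shape[0] // 2
    out[lo : lo + a.shape[0], lo : lo + a.shape[0]] = a
    return out
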