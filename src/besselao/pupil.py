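"""Pupil- and focal-plane fields and Fourier propagation between them.

Coordinates on the pupil grid are direction cosines scaled by the medium
index, i.e. numerical-aperture (NA) units; the focal plane is sampled on the
conjugate grid with pitch ``wavelength / (N_pad * dna)``.  Propagation is a
unitary (norm-preserving) centered FFT, with zero-padding by the configured
oversampling factor so that the focal field is well sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .config import OpticalConfig


def wrap_phase(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap phase values to the repo-wide convention (-pi, pi]."""
    wrapped = np.angle(np.exp(1j * np.asarray(phi, dtype=float)))
    # np.angle returns [-pi, pi]; fold the single -pi value onto +pi
    wrapped = np.where(wrapped == -np.pi, np.pi, wrapped)
    return wrapped if np.ndim(phi) else float(wrapped)


@dataclass
class PupilField:
    """Complex field sampled on a square grid at the objective back pupil.

    Attributes
    ----------
    values:
        Complex (n, n) array, grid centered at index ``n // 2``.
    na_per_px:
        Pixel pitch in NA units.
    na_pupil:
        NA of the objective disk; masking operations zero everything outside.
    wavelength_um:
        Vacuum wavelength the field is defined at.
    """

    values: np.ndarray
    na_per_px: float
    na_pupil: float
    wavelength_um: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("pupil field must be square")
        if v.shape[0] % 2:
            raise ValueError("pupil field must have even side length")
        self.values = v.astype(complex)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def na_axes(self) -> np.ndarray:
        """1-D NA coordinate of pixel centers (same for both axes)."""
        n = self.n
        return (np.arange(n) - n // 2) * self.na_per_px

    def na_radius(self) -> np.ndarray:
        ax = self.na_axes()
        return np.hypot(ax[None, :], ax[:, None])

    def azimuth(self) -> np.ndarray:
        ax = self.na_axes()
        return np.arctan2(ax[:, None], ax[None, :])

    def disk_mask(self, threshold: float = 0.5) -> np.ndarray:
        """Boolean mask of pixels inside the objective NA disk."""
        return disk_amplitude(self.na_radius(), self.na_pupil, self.na_per_px) > threshold

    @property
    def energy(self) -> float:
        return float(np.sum(np.abs(self.values) ** 2))

    def copy_with(self, values: np.ndarray) -> "PupilField":
        return replace(self, values=np.asarray(values, dtype=complex))

    def masked(self) -> "PupilField":
        """Zero the field outside the objective NA disk (hard edge)."""
        out = self.values.copy()
        out[self.na_radius() > self.na_pupil] = 0.0
        return self.copy_with(out)


@dataclass
class FocalField:
    """Complex field on the plane conjugate to the objective focal plane."""

    values: np.ndarray
    pitch_um: float
    wavelength_um: float

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def energy(self) -> float:
        return float(np.sum(np.abs(self.values) ** 2))


@dataclass
class FocalPattern:
    """Phase-only map (radians, wrapped to (-pi, pi]) for the focal-plane SLM."""

    phase: np.ndarray
    pitch_um: float

    def __post_init__(self) -> None:
        self.phase = np.asarray(wrap_phase(np.asarray(self.phase, dtype=float)))

    @property
    def n(self) -> int:
        return self.phase.shape[0]

    def to_uint8(self) -> np.ndarray:
        """Export for an 8-bit SLM: the 256-level LUT maps [0, 2*pi) onto
        0..255 (step 2*pi/256), so gray level g encodes phase g/256 * 2*pi
        and the export/import round trip is bit-exact."""
        frac = np.mod(self.phase, 2 * np.pi) / (2 * np.pi)
        # small tolerance so re-quantizing an exact level value is stable
        return np.minimum(np.floor(frac * 256 + 1e-6), 255).astype(np.uint8)

    @classmethod
    def from_uint8(cls, img: np.ndarray, pitch_um: float) -> "FocalPattern":
        return cls(phase=img.astype(float) / 256.0 * 2 * np.pi, pitch_um=pitch_um)


def disk_amplitude(rho: np.ndarray, radius: float, pitch: float) -> np.ndarray:
    """Anti-aliased indicator of ``rho <= radius`` (linear edge over one pixel)."""
    if radius <= 0:
        out = np.zeros_like(rho)
        out[rho == rho.min()] = 1.0
        return out
    return np.clip((radius - rho) / pitch + 0.5, 0.0, 1.0)


def make_pupil_grid(config: OpticalConfig) -> PupilField:
    """Uniform unit-amplitude, zero-phase field filling the objective NA disk.

    The disk edge is anti-aliased over one pixel so that disk-area and
    annulus-energy ratios converge at moderate grid sizes.
    """
    if config.grid_n < 32:
        raise ValueError(
            "grid_n too small to sample the pupil disk: need grid_n >= 32 "
            f"(disk diameter grid_n/2 px), got {config.grid_n}"
        )
    n = config.grid_n
    ax = (np.arange(n) - n // 2) * config.na_per_px
    rho = np.hypot(ax[None, :], ax[:, None])
    amp = disk_amplitude(rho, config.na_objective, config.na_per_px)
    return PupilField(
        values=amp.astype(complex),
        na_per_px=config.na_per_px,
        na_pupil=config.na_objective,
        wavelength_um=config.wavelength_um,
    )


def _centered_fft2(a: np.ndarray, inverse: bool = False) -> np.ndarray:
    f = np.fft.ifft2 if inverse else np.fft.fft2
    return np.fft.fftshift(f(np.fft.ifftshift(a), norm="ortho"))


def _pad_center(a: np.ndarray, n_out: int) -> np.ndarray:
    n = a.shape[0]
    if n_out == n:
        return a
    out = np.zeros((n_out, n_out), dtype=a.dtype)
    lo = n_out // 2 - n // 2
    out[lo : lo + n, lo : lo + n] = a
    return out


def _crop_center(a: np.ndarray, n_out: int) -> np.ndarray:
    n = a.shape[0]
    if n_out == n:
        return a
    lo = n // 2 - n_out // 2
    return a[lo : lo + n_out, lo : lo + n_out]


def propagate(
    field: PupilField | FocalField,
    direction: Literal["pupil_to_focal", "focal_to_pupil"] | None = None,
    config: OpticalConfig | None = None,
    *,
    oversampling: float | None = None,
    crop_to: int | None = None,
) -> FocalField | PupilField:
    """Propagate between the pupil plane and its Fourier-conjugate focal plane.

    Pupil -> focal zero-pads by the oversampling factor and applies a unitary
    centered FFT; focal -> pupil inverts it.  Round-tripping a pupil field
    therefore reproduces it exactly (up to floating point), and energy is
    conserved by Parseval's theorem.

    Parameters
    ----------
    direction:
        Inferred from the input type when omitted.
    oversampling:
        Padding factor for pupil -> focal (default: config value, or 1 for a
        bare :class:`PupilField` without a config).
    crop_to:
        For focal -> pupil, crop the result back to this side length
        (default: no cropping).
    """
    if direction is None:
        direction = "pupil_to_focal" if isinstance(field, PupilField) else "focal_to_pupil"

    if direction == "pupil_to_focal":
        if not isinstance(field, PupilField):
            raise TypeError("pupil_to_focal expects a PupilField")
        ov = oversampling if oversampling is not None else (config.pupil_oversampling if config else 1.0)
        n_pad = int(round(field.n * ov))
        if n_pad % 2:
            n_pad += 1
        focal = _centered_fft2(_pad_center(field.values, n_pad))
        pitch = field.wavelength_um / (n_pad * field.na_per_px)
        return FocalField(values=focal, pitch_um=pitch, wavelength_um=field.wavelength_um)

    if direction == "focal_to_pupil":
        if not isinstance(field, FocalField):
            raise TypeError("focal_to_pupil expects a FocalField")
        back = _centered_fft2(field.values, inverse=True)
        na_per_px = field.wavelength_um / (field.n * field.pitch_um)
        if crop_to is not None:
            back = _crop_center(back, crop_to)
        na_pupil = config.na_objective if config else na_per_px * back.shape[0] / 4
        return PupilField(
            values=back,
            na_per_px=na_per_px,
            na_pupil=na_pupil,
            wavelength_um=field.wavelength_um,
        )

    raise ValueError(f"unknown direction {direction!r}")
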