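"""Optical system configuration.

The model system is a two-photon fluorescence microscope in which a
phase-only SLM conjugate to the objective focal plane (SLM1) shapes the
excitation into a Bessel focus through an annular amplitude mask, and a
second SLM conjugate to the objective back pupil (SLM2) is used for
pupil-plane wavefront control.  All simulations work in pupil coordinates
expressed in numerical-aperture (NA) units, so the only hardware numbers
that enter are the wavelength, immersion index, objective NA/magnification,
tube-lens focal length and the relay chain that images the annular mask
onto the back pupil.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

#: Relay chain from the annular-mask plane to the objective back pupil,
#: listed as consecutive (f_in, f_out) lens pairs in mm: mask -> galvos
#: (750/350), galvo-galvo conjugation (30/30), beam expansion onto SLM2
#: (30/150), SLM2 -> back pupil (120/240).
DEFAULT_RELAY_FOCALS_MM = (750.0, 350.0, 30.0, 30.0, 30.0, 150.0, 120.0, 240.0)


@dataclass(frozen=True)
class OpticalConfig:
    """Parameters of the excitation path.

    Defaults describe a 940-nm femtosecond beam focused by a 25x / 1.05-NA
    water-dipping objective (200-mm tube lens) with the annular mask relayed
    to the pupil through the lens chain in :data:`DEFAULT_RELAY_FOCALS_MM`.

    Parameters
    ----------
    wavelength_um:
        Excitation (vacuum) wavelength in micrometres.
    n_medium:
        Refractive index of the immersion/sample medium.
    na_objective:
        Numerical aperture of the objective; must be < ``n_medium``.
    objective_magnification, tube_lens_focal_mm:
        Define the objective focal length ``f_obj = f_tube / M`` and hence
        the physical back-pupil radius ``NA * f_obj``.
    relay_focals_mm:
        Even-length sequence of focal lengths (mm), consecutive pairs being
        4f relays from the mask plane to the pupil plane.
    grid_n:
        Pixels per side of the pupil-plane grid.  The pupil disk diameter is
        ``grid_n / 2`` pixels, i.e. the grid extends to twice the objective
        NA, which keeps the focal field Nyquist-sampled before padding.
    pupil_oversampling:
        Zero-padding factor applied before Fourier propagation; the focal
        pixel pitch is ``wavelength / (grid_n * pupil_oversampling * dna)``.
    """

    wavelength_um: float = 0.94
    n_medium: float = 1.33
    na_objective: float = 1.05
    objective_magnification: float = 25.0
    tube_lens_focal_mm: float = 200.0
    relay_focals_mm: tuple[float, ...] = field(default=DEFAULT_RELAY_FOCALS_MM)
    grid_n: int = 256
    pupil_oversampling: float = 2.0

    def __post_init__(self) -> None:
        if self.wavelength_um <= 0:
            raise ValueError("wavelength must be positive")
        if not (0 < self.na_objective < self.n_medium):
            raise ValueError("need 0 < na_objective < n_medium")
        if self.grid_n % 2 or self.grid_n < 16:
            raise ValueError("grid_n must be even and >= 16")
        if self.pupil_oversampling < 1:
            raise ValueError("pupil_oversampling must be >= 1")
        if len(self.relay_focals_mm) % 2:
            raise ValueError("relay_focals_mm must pair up into 4f relays")
        object.__setattr__(self, "relay_focals_mm", tuple(float(f) for f in self.relay_focals_mm))

    # ---- derived geometry -------------------------------------------------

    @property
    def objective_focal_mm(self) -> float:
        return self.tube_lens_focal_mm / self.objective_magnification

    @property
    def pupil_radius_mm(self) -> float:
        """Physical radius of the objective back pupil (NA * f_obj)."""
        return self.na_objective * self.objective_focal_mm

    @property
    def relay_magnification(self) -> float:
        """Transverse magnification from the mask plane to the pupil plane."""
        mag = 1.0
        focals = self.relay_focals_mm
        for i in range(0, len(focals), 2):
            mag *= focals[i + 1] / focals[i]
        return mag

    @property
    def na_max(self) -> float:
        """NA at the edge of the pupil grid (2x objective NA by construction)."""
        return 2.0 * self.na_objective

    @property
    def na_per_px(self) -> float:
        """Pupil-grid pixel pitch in NA units."""
        return 2.0 * self.na_max / self.grid_n

    @property
    def padded_n(self) -> int:
        return int(round(self.grid_n * self.pupil_oversampling))

    @property
    def focal_pitch_um(self) -> float:
        """Focal-plane pixel pitch after padded Fourier propagation."""
        return self.wavelength_um / (self.padded_n * self.na_per_px)

    @property
    def k0(self) -> float:
        """Vacuum wavenumber in rad/um."""
        return 2.0 * math.pi / self.wavelength_um

    # ---- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "wavelength_um": self.wavelength_um,
            "n_medium": self.n_medium,
            "na_objective": self.na_objective,
            "objective_magnification": self.objective_magnification,
            "tube_lens_focal_mm": self.tube_lens_focal_mm,
            "relay_focals_mm": list(self.relay_focals_mm),
            "grid_n": self.grid_n,
            "pupil_oversampling": self.pupil_oversampling,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalConfig":
        return cls(**{k: (tuple(v) if k == "relay_focals_mm" else v) for k, v in d.items()})

    @classmethod
    def load(cls, path: str | Path) -> "OpticalConfig":
        """Read a configuration from a JSON or YAML file."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in {".yml", ".yaml"}:
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() in {".yml", ".yaml"}:
            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))

    def with_grid(self, grid_n: int | None = None, pupil_oversampling: float | None = None) -> "OpticalConfig":
        """Copy with a different sampling (physics parameters unchanged)."""
        kw = {}
        if grid_n is not None:
            kw["grid_n"] = grid_n
        if pupil_oversampling is not None:
            kw["pupil_oversampling"] = pupil_oversampling
        return replace(self, **kw)
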