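"""Zernike polynomial basis on the objective pupil disk.

Conventions (fixed repo-wide):

* Polynomials are the un-normalized Born & Wolf circle polynomials
  ``Z_n^m(rho, theta) = R_n^{|m|}(rho) * cos(m theta)`` for ``m >= 0`` and
  ``R_n^{|m|}(rho) * sin(|m| theta)`` for ``m < 0``, so ``R_n^{|m|}(1) = 1``
  and defocus is ``2 rho^2 - 1``.  A coefficient of "1 wave" therefore means
  the peak polynomial value contributes one wavelength of path difference.
* Mode ordering: ``(n, m)`` sorted by radial order ``n`` ascending, then
  azimuthal index ``m`` ascending.  Radial orders 0..9 give exactly 55
  modes ("first 55 modes").
* ``rho`` is pupil radius normalized to the objective NA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .pupil import PupilField

ModeIndex = tuple[int, int]

# named low-order aberrations
PISTON: ModeIndex = (0, 0)
TIP: ModeIndex = (1, 1)
TILT: ModeIndex = (1, -1)
DEFOCUS: ModeIndex = (2, 0)
ASTIGMATISM: ModeIndex = (2, 2)
COMA: ModeIndex = (3, 1)
TREFOIL: ModeIndex = (3, 3)
SPHERICAL: ModeIndex = (4, 0)


def zernike_modes(n_max: int) -> list[ModeIndex]:
    """All valid (n, m) pairs through radial order ``n_max``, fixed ordering."""
    return [(n, m) for n in range(n_max + 1) for m in range(-n, n + 1, 2)]


#: The "first 55 modes": radial orders 0..9.
MODES_55: tuple[ModeIndex, ...] = tuple(zernike_modes(9))


def _check_mode(n: int, m: int) -> None:
    if n < 0 or abs(m) > n or (n - abs(m)) % 2:
        raise IndexError(f"invalid Zernike index (n={n}, m={m})")


def radial_poly(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    """Radial polynomial R_n^{|m|}(rho)."""
    _check_mode(n, m)
    m = abs(m)
    rho = np.asarray(rho, dtype=float)
    out = np.zeros_like(rho)
    for k in range((n - m) // 2 + 1):
        c = (
            (-1) ** k
            * math.factorial(n - k)
            / (math.factorial(k) * math.factorial((n + m) // 2 - k) * math.factorial((n - m) // 2 - k))
        )
        out += c * rho ** (n - 2 * k)
    return out


def zernike_eval(n: int, m: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Evaluate Z_n^m at polar coordinates (no disk clipping)."""
    r = radial_poly(n, m, rho)
    if m > 0:
        return r * np.cos(m * theta)
    if m < 0:
        return r * np.sin(-m * theta)
    return r


def zernike_surface(n: int, m: int, pupil: PupilField, clip: bool = True) -> np.ndarray:
    """Z_n^m sampled on a pupil grid, ``rho`` scaled to the objective NA.

    With ``clip`` (default) the surface is zeroed outside the NA disk; with
    ``clip=False`` the polynomial is evaluated everywhere, which is what
    gradient-based computations near the disk edge need.
    """
    _check_mode(n, m)
    rho = pupil.na_radius() / pupil.na_pupil
    surf = zernike_eval(n, m, rho, pupil.azimuth())
    if clip:
        surf = np.where(rho <= 1.0, surf, 0.0)
    return surf


@dataclass
class ZernikeCoefficients:
    """Mapping (n, m) -> amplitude in waves over a fixed mode ordering."""

    amplitudes: dict[ModeIndex, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (n, m) in self.amplitudes:
            _check_mode(n, m)
        self.amplitudes = {k: float(v) for k, v in self.amplitudes.items()}

    # -- mapping-ish interface ---------------------------------------------

    def __getitem__(self, mode: ModeIndex) -> float:
        return self.amplitudes.get(mode, 0.0)

    def __iter__(self):
        return iter(self.amplitudes.items())

    def __len__(self) -> int:
        return len(self.amplitudes)

    @property
    def mode_count(self) -> int:
        return len(self.amplitudes)

    def to_vector(self, modes: Sequence[ModeIndex] = MODES_55) -> np.ndarray:
        return np.array([self[mode] for mode in modes], dtype=float)

    @classmethod
    def from_vector(cls, vec: np.ndarray, modes: Sequence[ModeIndex] = MODES_55) -> "ZernikeCoefficients":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (len(modes),):
            raise ValueError("coefficient vector length does not match mode list")
        return cls({mode: float(v) for mode, v in zip(modes, vec)})

    def surface(self, pupil: PupilField, clip: bool = True) -> np.ndarray:
        """Synthesize the wavefront (waves) on a pupil grid."""
        out = np.zeros((pupil.n, pupil.n))
        for (n, m), a in self.amplitudes.items():
            if a != 0.0:
                out += a * zernike_surface(n, m, pupil, clip=clip)
        return out

    def remove(self, modes: Iterable[ModeIndex]) -> "ZernikeCoefficients":
        """Copy with the listed modes zeroed (absent modes are a no-op)."""
        drop = set(modes)
        return ZernikeCoefficients({k: v for k, v in self.amplitudes.items() if k not in drop})

    def nonzero(self, tol: float = 0.0) -> "ZernikeCoefficients":
        return ZernikeCoefficients({k: v for k, v in self.amplitudes.items() if abs(v) > tol})


def remove_modes(coeffs: ZernikeCoefficients, modes: Iterable[ModeIndex]) -> ZernikeCoefficients:
    """Zero the listed modes; all other coefficients are unchanged."""
    return coeffs.remove(modes)


_BASIS_CACHE: dict[tuple, np.ndarray] = {}


def _basis_matrix(pupil: PupilField, modes: Sequence[ModeIndex], mask: np.ndarray) -> np.ndarray:
    key = (pupil.n, pupil.na_per_px, pupil.na_pupil, tuple(modes), mask.tobytes())
    cached = _BASIS_CACHE.get(key)
    if cached is not None:
        return cached
    cols = [zernike_surface(n, m, pupil)[mask] for (n, m) in modes]
    A = np.column_stack(cols)
    if len(_BASIS_CACHE) > 8:
        _BASIS_CACHE.clear()
    _BASIS_CACHE[key] = A
    return A


def fit_zernike(
    wavefront: np.ndarray,
    pupil: PupilField,
    n_modes: int = 55,
    mask: np.ndarray | None = None,
) -> tuple[ZernikeCoefficients, np.ndarray]:
    """Least-squares projection of a wavefront map onto the first ``n_modes``.

    Parameters
    ----------
    wavefront:
        Real map in waves, defined at least on the pupil disk (NaNs and
        pixels outside the disk are ignored).
    pupil:
        Grid geometry (values are not used).
    n_modes:
        Leading count of modes in the fixed ordering; at most 55.
    mask:
        Optional boolean map restricting the fit support further.

    Returns
    -------
    (coefficients, residual)
        Residual is ``wavefront - reconstruction`` on the fit support and 0
        elsewhere.
    """
    if n_modes < 1 or n_modes > len(MODES_55):
        raise ValueError(f"n_modes must be in 1..{len(MODES_55)}")
    modes = MODES_55[:n_modes]
    wavefront = np.asarray(wavefront, dtype=float)
    support = pupil.disk_mask() & np.isfinite(wavefront)
    if mask is not None:
        support &= mask
    n_valid = int(support.sum())
    if n_valid < n_modes:
        raise ValueError(f"only {n_valid} valid pixels for {n_modes} modes")
    A = _basis_matrix(pupil, modes, support)
    sol, _, rank, _ = np.linalg.lstsq(A, wavefront[support], rcond=None)
    if rank < n_modes:
        import warnings

        warnings.warn(f"rank-deficient Zernike fit (rank {rank} < {n_modes})", stacklevel=2)
    coeffs = ZernikeCoefficients.from_vector(sol, modes)
    residual = np.zeros_like(wavefront)
    residual[support] = wavefront[support] - A @ sol
    return coeffs, residual


def wavefront_rms(wavefront: np.ndarray, pupil: PupilField) -> float:
    """RMS of a wavefront map over the pupil disk (waves)."""
    m = pupil.disk_mask()
    return float(np.sqrt(np.mean(np.square(wavefront[m]))))
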