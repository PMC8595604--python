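"""Pupil-segmentation indirect wavefront sensing (simulation + reconstruction).

The back pupil is divided into k x k square tiles (default 5 x 5).  Each
tile is illuminated in turn; the beamlet it admits focuses to a spot whose
lateral displacement from a reference position is proportional to the mean
wavefront gradient over the tile.  Collecting the per-tile displacements of
a fluorescent-bead image therefore samples the wavefront slope field, which
is integrated by a modal least-squares fit in the Zernike basis.

Shift/gradient calibration: a wavefront tilt of ``g`` waves per NA unit
displaces the focus by ``g * lambda`` micrometres (Fourier shift theorem in
the NA <-> x/lambda conjugate pair).  The forward simulator and the
reconstructor share this one constant, so the closed loop is self-consistent
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from skimage.registration import phase_cross_correlation

from .config import OpticalConfig
from .psf import apodization
from .pupil import PupilField, _crop_center, make_pupil_grid, propagate
from .zernike import (
    MODES_55,
    ModeIndex,
    ZernikeCoefficients,
    zernike_surface,
)

EXCLUDED_MODES: tuple[ModeIndex, ...] = ((0, 0), (1, -1), (1, 1))  # piston/tip/tilt null space


@dataclass
class SegmentGrid:
    """Partition of the pupil disk into k x k square tiles.

    Tiles are laid over the disk's bounding box; a tile is valid when at
    least ``min_inside_fraction`` of its area overlaps the disk, and
    reconstruction weights tiles by their inside area.
    """

    k: int
    na_pupil: float
    min_inside_fraction: float = 0.25

    def tile_bounds(self, i: int, j: int) -> tuple[float, float, float, float]:
        """(na_x_lo, na_x_hi, na_y_lo, na_y_hi) of tile (row i, col j)."""
        w = 2 * self.na_pupil / self.k
        return (
            -self.na_pupil + j * w,
            -self.na_pupil + (j + 1) * w,
            -self.na_pupil + i * w,
            -self.na_pupil + (i + 1) * w,
        )

    def tile_masks(self, pupil: PupilField) -> list[dict]:
        """Per-tile pixel masks and metadata on a pupil grid.

        Returns dicts with keys ``index`` (i, j), ``mask`` (tile-and-disk
        pixels), ``inside_fraction``, ``valid``, ``centroid_na``.
        """
        ax = pupil.na_axes()
        X, Y = np.meshgrid(ax, ax)
        disk = pupil.disk_mask()
        tiles = []
        for i in range(self.k):
            for j in range(self.k):
                x0, x1, y0, y1 = self.tile_bounds(i, j)
                in_tile = (X >= x0) & (X < x1) & (Y >= y0) & (Y < y1)
                n_tile = int(in_tile.sum())
                mask = in_tile & disk
                frac = mask.sum() / n_tile if n_tile else 0.0
                sel = mask if mask.any() else in_tile
                tiles.append(
                    {
                        "index": (i, j),
                        "mask": mask,
                        "inside_fraction": float(frac),
                        "valid": frac >= self.min_inside_fraction,
                        "centroid_na": (float(X[sel].mean()), float(Y[sel].mean())),
                    }
                )
        return tiles

    @property
    def n_tiles(self) -> int:
        return self.k * self.k


def default_segment_grid(config: OpticalConfig, k: int = 5) -> SegmentGrid:
    return SegmentGrid(k=k, na_pupil=config.na_objective)


@dataclass
class SegmentShiftMap:
    """Per-tile bead-image displacements (um at the sample plane)."""

    shifts_um: np.ndarray  # (n_tiles, 2) as (dx, dy); NaN for invalid tiles
    valid: np.ndarray  # (n_tiles,) bool
    confidence: np.ndarray  # (n_tiles,) correlation-peak confidence
    reference: str = "full_pupil"

    def __post_init__(self) -> None:
        self.shifts_um = np.asarray(self.shifts_um, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.confidence = np.asarray(self.confidence, dtype=float)


def _bead_kernel_2d(bead_diameter_um: float, pitch_um: float) -> np.ndarray:
    """Projected thickness of a uniform fluorescent sphere, unit sum."""
    r_px = bead_diameter_um / 2 / pitch_um
    n = max(3, int(2 * np.ceil(r_px) + 1))
    ax = np.arange(n) - n // 2
    rr2 = ax[None, :] ** 2 + ax[:, None] ** 2
    k = np.sqrt(np.clip(r_px**2 - rr2, 0.0, None))
    s = k.sum()
    if s == 0:  # bead below pixel size: delta kernel
        k[n // 2, n // 2] = 1.0
        return k
    return k / s


def _tile_image(
    aberrated: np.ndarray,
    tile_mask: np.ndarray,
    pupil: PupilField,
    config: OpticalConfig,
    window_px: int,
    bead: np.ndarray | None,
) -> np.ndarray:
    from scipy.signal import fftconvolve

    f = propagate(pupil.copy_with(aberrated * tile_mask), "pupil_to_focal", config)
    img = _crop_center(np.abs(f.values) ** 4, window_px)
    if bead is not None and bead.size > 1:
        img = fftconvolve(img, bead, mode="same")
    return img


def simulate_segment_images(
    true_wavefront: np.ndarray,
    config: OpticalConfig,
    *,
    segments: SegmentGrid | None = None,
    bead_diameter_um: float = 2.0,
    window_px: int = 128,
    photon_budget: float | None = None,
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Two-photon bead images for single-tile illumination of the pupil.

    Each tile image is the two-photon focal intensity of the tile-restricted
    aberrated pupil, convolved with the bead's projected profile; a final
    ``reference`` image uses the full pupil.  ``photon_budget`` (expected
    photons in the brightest reference pixel) turns on Poisson noise.

    Returns ``{"images": (n_tiles, w, w), "reference": (w, w),
    "tiles": [...], "pitch_um": float, "empty": [tile indices]}``.
    """
    segments = segments or default_segment_grid(config)
    pupil = make_pupil_grid(config)
    true_wavefront = np.asarray(true_wavefront, dtype=float)
    aberrated = pupil.values * apodization(pupil, config) * np.exp(2j * np.pi * true_wavefront)
    bead = _bead_kernel_2d(bead_diameter_um, config.focal_pitch_um) if bead_diameter_um > 0 else None
    flat = pupil.values * apodization(pupil, config)
    tiles = segments.tile_masks(pupil)
    images = np.zeros((len(tiles), window_px, window_px))
    templates = np.zeros_like(images)
    empty = []
    for t, tile in enumerate(tiles):
        if not tile["mask"].any():
            empty.append(t)
            continue
        images[t] = _tile_image(aberrated, tile["mask"], pupil, config, window_px, bead)
        templates[t] = _tile_image(flat, tile["mask"], pupil, config, window_px, bead)
    reference = _tile_image(aberrated, np.ones_like(pupil.values.real), pupil, config, window_px, bead)
    if photon_budget is not None:
        rng = np.random.default_rng(rng)
        scale = photon_budget / reference.max()
        images = rng.poisson(images * scale).astype(float) / scale
        reference = rng.poisson(reference * scale).astype(float) / scale
    return {
        "images": images,
        "reference": reference,
        "templates": templates,
        "tiles": tiles,
        "pitch_um": config.focal_pitch_um,
        "empty": empty,
    }


def estimate_shifts(
    images: np.ndarray,
    reference: np.ndarray,
    pitch_um: float,
    *,
    method: Literal["template", "xcorr", "com"] = "template",
    templates: np.ndarray | None = None,
    upsample: int = 50,
    snr_threshold: float = 1e-6,
) -> SegmentShiftMap:
    """Sub-pixel displacement of each tile image relative to its reference.

    ``template`` (default) registers each tile image by upsampled
    cross-correlation against the matching zero-aberration tile image — the
    calibration images an instrument records once without a sample.  It is
    model-matched (blob against identically shaped blob) and robust to the
    mild defocus/curvature distortion a tile beamlet picks up inside strong
    aberrations.  ``xcorr`` registers against the full-pupil ``reference``
    image; ``com`` compares intensity centroids with the reference's.

    Tiles whose total signal falls below ``snr_threshold`` times the
    reference total are marked invalid.  Confidence is the normalized
    correlation peak (1 for ``com``).
    """
    images = np.asarray(images, dtype=float)
    ref_total = reference.sum()
    n = len(images)
    shifts = np.full((n, 2), np.nan)
    valid = np.zeros(n, dtype=bool)
    conf = np.zeros(n)
    ref_com = _center_of_mass(reference)
    if method == "template" and templates is None:
        raise ValueError("method 'template' needs the zero-aberration tile images")
    for t, img in enumerate(images):
        if img.sum() <= snr_threshold * ref_total:
            continue
        if method in ("template", "xcorr"):
            target = templates[t] if method == "template" else reference
            if target.sum() <= 0:
                continue
            # skimage convention: shift that registers `img` onto `target`
            (dy, dx), error, _ = phase_cross_correlation(
                target, img, upsample_factor=upsample, normalization=None
            )
            shifts[t] = (-dx * pitch_um, -dy * pitch_um)
            conf[t] = max(0.0, 1.0 - float(error))
        elif method == "com":
            cy, cx = _center_of_mass(img)
            shifts[t] = ((cx - ref_com[1]) * pitch_um, (cy - ref_com[0]) * pitch_um)
            conf[t] = 1.0
        else:
            raise ValueError("method must be 'template', 'xcorr' or 'com'")
        valid[t] = True
    return SegmentShiftMap(shifts_um=shifts, valid=valid, confidence=conf)


def _center_of_mass(img: np.ndarray) -> tuple[float, float]:
    tot = img.sum()
    iy = np.arange(img.shape[0])
    ix = np.arange(img.shape[1])
    return float((img.sum(axis=1) @ iy) / tot), float((img.sum(axis=0) @ ix) / tot)


def _tile_gradient_matrix(
    tiles: list[dict],
    pupil: PupilField,
    modes: list[ModeIndex],
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Rows: mean (d/dna_x, d/dna_y) of each mode over each valid tile."""
    step = pupil.na_per_px
    valid_idx = [t for t, tile in enumerate(tiles) if tile["valid"] and tile["mask"].any()]
    A = np.zeros((2 * len(valid_idx), len(modes)))
    w = np.zeros(2 * len(valid_idx))
    for col, (n, m) in enumerate(modes):
        surf = zernike_surface(n, m, pupil, clip=False)
        gy, gx = np.gradient(surf, step)
        for r, t in enumerate(valid_idx):
            mask = tiles[t]["mask"]
            A[2 * r, col] = gx[mask].mean()
            A[2 * r + 1, col] = gy[mask].mean()
            w[2 * r] = w[2 * r + 1] = tiles[t]["inside_fraction"]
    return A, w, valid_idx


def reconstruct_wavefront(
    shifts: SegmentShiftMap,
    config: OpticalConfig,
    *,
    segments: SegmentGrid | None = None,
    n_modes: int = 21,
) -> tuple[np.ndarray, ZernikeCoefficients]:
    """Modal least-squares integration of tile shifts into a wavefront.

    Shifts are converted to mean phase gradients (waves per NA unit) via the
    shared ``g = shift / lambda`` calibration and fitted against the mean
    gradients of the Zernike modes over each tile, weighted by tile inside
    area.  Piston, tip and tilt are indeterminate (piston has no gradient;
    tip/tilt only move the reference position) and are returned as zero.

    ``n_modes`` counts leading modes of the fixed ordering; when the valid
    tiles provide fewer than ``n_modes`` gradient equations the mode count
    is reduced with a warning.

    Returns the reconstructed map (waves, on the pupil grid) and its
    coefficients.
    """
    import warnings

    segments = segments or default_segment_grid(config)
    pupil = make_pupil_grid(config)
    tiles = segments.tile_masks(pupil)
    ok = shifts.valid.copy()
    for t, tile in enumerate(tiles):
        if not tile["valid"]:
            ok[t] = False
    n_valid = int(ok.sum())
    if n_valid < 3:
        raise ValueError(f"need >= 3 valid tiles, have {n_valid}")

    modes = [mode for mode in MODES_55[:n_modes] if mode not in EXCLUDED_MODES]
    if len(modes) > 2 * n_valid:
        keep = 2 * n_valid
        warnings.warn(
            f"{n_valid} tiles support only {keep} gradient equations; "
            f"reducing mode count from {len(modes)}",
            stacklevel=2,
        )
        modes = modes[:keep]

    tiles_for_fit = [
        {**tile, "valid": tile["valid"] and shifts.valid[t]} for t, tile in enumerate(tiles)
    ]
    A, w, valid_idx = _tile_gradient_matrix(tiles_for_fit, pupil, modes)
    g = np.empty(2 * len(valid_idx))
    for r, t in enumerate(valid_idx):
        g[2 * r] = shifts.shifts_um[t, 0] / config.wavelength_um
        g[2 * r + 1] = shifts.shifts_um[t, 1] / config.wavelength_um
    # tip/tilt is declared null space: remove the (weighted) uniform shift
    # component explicitly so it cannot leak into higher modes
    wx = w[0::2]
    g[0::2] -= np.average(g[0::2], weights=wx)
    g[1::2] -= np.average(g[1::2], weights=wx)
    sw = np.sqrt(w)
    sol, *_ = np.linalg.lstsq(A * sw[:, None], g * sw, rcond=None)
    coeffs = ZernikeCoefficients({mode: float(c) for mode, c in zip(modes, sol)})
    return coeffs.surface(pupil), coeffs


def sense_and_reconstruct(
    true_wavefront: np.ndarray,
    config: OpticalConfig,
    *,
    segments: SegmentGrid | None = None,
    bead_diameter_um: float = 2.0,
    photon_budget: float | None = None,
    n_modes: int = 21,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, ZernikeCoefficients]:
    """Full sensing loop: simulate tile images, register, reconstruct."""
    sim = simulate_segment_images(
        true_wavefront,
        config,
        segments=segments,
        bead_diameter_um=bead_diameter_um,
        photon_budget=photon_budget,
        rng=rng,
    )
    shifts = estimate_shifts(
        sim["images"], sim["reference"], sim["pitch_um"], templates=sim["templates"]
    )
    return reconstruct_wavefront(shifts, config, segments=segments, n_modes=n_modes)
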