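"""Readers and writers for the package's standard on-disk formats.

Wavefront maps travel as 32-bit float single-plane TIFF or as
whitespace-delimited text matrices; Zernike coefficient vectors as CSV with
columns ``n, m, waves``; SLM patterns as 8-bit grayscale images (0-255
mapping [0, 2*pi)) or float TIFF; PSF volumes as multi-page float TIFF with
voxel-size metadata; reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .pupil import FocalPattern
from .psf import FwhmReport, PSFVolume
from .zernike import ZernikeCoefficients


def read_wavefront(path: str | Path) -> np.ndarray:
    """Read a wavefront map (waves) from float TIFF or a text matrix."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return tifffile.imread(path).astype(float)
    return np.loadtxt(path, dtype=float)


def write_wavefront(path: str | Path, wavefront: np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, np.asarray(wavefront, dtype=np.float32))
    else:
        np.savetxt(path, np.asarray(wavefront, dtype=float))


def read_zernike_csv(path: str | Path) -> ZernikeCoefficients:
    df = pd.read_csv(path)
    return ZernikeCoefficients(
        {(int(row["n"]), int(row["m"])): float(row["waves"]) for _, row in df.iterrows()}
    )


def write_zernike_csv(path: str | Path, coeffs: ZernikeCoefficients) -> None:
    rows = [{"n": n, "m": m, "waves": a} for (n, m), a in coeffs]
    pd.DataFrame(rows, columns=["n", "m", "waves"]).to_csv(path, index=False)


def write_pattern(path: str | Path, pattern: FocalPattern, *, bits: int = 8) -> None:
    """Export an SLM pattern: 8-bit grayscale (PNG/TIFF) or float TIFF."""
    path = Path(path)
    if bits == 8:
        img = pattern.to_uint8()
        if path.suffix.lower() == ".png":
            from PIL import Image

            Image.fromarray(img).save(path)
        else:
            tifffile.imwrite(path, img)
    else:
        tifffile.imwrite(path, pattern.phase.astype(np.float32))


def read_pattern(path: str | Path, pitch_um: float) -> FocalPattern:
    path = Path(path)
    if path.suffix.lower() == ".png":
        from PIL import Image

        arr = np.asarray(Image.open(path))
    else:
        arr = tifffile.imread(path)
    if arr.dtype == np.uint8:
        return FocalPattern.from_uint8(arr, pitch_um)
    return FocalPattern(phase=arr.astype(float), pitch_um=pitch_um)


def write_psf(path: str | Path, psf: PSFVolume) -> None:
    """Multi-page float32 TIFF with voxel sizes in the ImageJ metadata."""
    dz = psf.axial_pitch_um
    tifffile.imwrite(
        path,
        psf.intensity.astype(np.float32),
        imagej=True,
        resolution=(1.0 / psf.lateral_pitch_um, 1.0 / psf.lateral_pitch_um),
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
    )


def write_report(path: str | Path, report: dict | FwhmReport) -> None:
    if isinstance(report, FwhmReport):
        report = vars(report)
    Path(path).write_text(json.dumps(_jsonable(report), indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
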