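"""Phantoms, forward imaging, deconvolution, spine detectability."""

import numpy as np
import pytest

from besselao.bessel import AnnularMaskSpec, annulus_field
from besselao.config import OpticalConfig
from besselao.imaging import (
    Phantom,
    _render_sphere,
    deconvolve,
    detect_spines,
    image_phantom,
    make_phantom,
)
from besselao.psf import PSFVolume, compute_psf, fwhm_1d, zernike_aberration
from besselao.pupil import make_pupil_grid


@pytest.fixture(scope="module")
def gaussian_psf():
    cfg = OpticalConfig(grid_n=256, pupil_oversampling=2.24)  # 0.1-um focal pitch
    disk = make_pupil_grid(cfg)
    zs = np.arange(-2.0, 2.0001, 0.1)
    return compute_psf(disk, zs, cfg, crop_to_px=48)


class TestPhantoms:
    def test_fixed_seed_is_bit_reproducible(self):
        a = make_phantom("dendrites", seed=11, n_spines=10)
        b = make_phantom("dendrites", seed=11, n_spines=10)
        assert np.array_equal(a.density, b.density)
        assert a.catalog == b.catalog

    def test_single_small_bead_is_compact(self):
        ph = make_phantom("beads", shape_um=(4, 4, 4), voxel_um=(0.1, 0.1, 0.1), n_beads=1, seed=0)
        assert len(ph.catalog) == 1
        nz = np.argwhere(ph.density > 0)
        assert nz.size > 0
        assert (nz.max(axis=0) - nz.min(axis=0)).max() <= 3  # ~0.1 um object

    def test_spine_catalog_bookkeeping(self):
        ph = make_phantom("dendrites", seed=3, n_spines=15)
        spines = [o for o in ph.catalog if o["type"] == "spine"]
        assert len(spines) == 15
        lo, hi = 0.5, 1.5
        for s in spines:
            assert lo <= s["diameter_um"] <= hi
            assert "anchor_um" in s  # attached to the dendrite polyline

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_phantom("axons")


class TestForwardImaging:
    def test_point_bead_image_matches_psf_axial_width(self, gaussian_psf):
        vox = (0.1, 0.1, 0.1)
        dens = np.zeros((41, 41, 41))
        _render_sphere(dens, vox, (2.0, 2.0, 2.0), 0.1)
        ph = Phantom(dens, vox)
        img = image_phantom(ph, gaussian_psf, "gaussian_stack")
        prof = img.values[:, 20, 20]
        bead_fwhm = fwhm_1d(np.arange(41) * 0.1, prof)
        tp = gaussian_psf.two_photon
        iz, iy, ix = np.unravel_index(np.argmax(tp), tp.shape)
        psf_fwhm = fwhm_1d(gaussian_psf.z_planes_um, tp[:, iy, ix])
        assert bead_fwhm == pytest.approx(psf_fwhm, rel=0.1)

    def test_bessel_projection_sees_beads_across_depth(self, cfg):
        # two beads 20 um apart axially: both in one Bessel frame, never in
        # one Gaussian plane
        ring = annulus_field(AnnularMaskSpec.from_hardware(cfg), cfg)
        zs = np.arange(-30.0, 30.001, 1.0)
        bessel_psf = compute_psf(ring, zs, cfg, crop_to_px=32)
        vox = (1.0, 0.5, 0.5)
        dens = np.zeros((61, 41, 41))
        _render_sphere(dens, vox, (20.0, 10.0, 5.0), 1.0)
        _render_sphere(dens, vox, (40.0, 10.0, 15.0), 1.0)
        ph = Phantom(dens, vox)
        proj = image_phantom(ph, bessel_psf, "bessel_projection")
        assert proj.values.ndim == 2
        peak_a = proj.values[18:22, 8:12].max()
        peak_b = proj.values[18:22, 28:32].max()
        floor = np.median(proj.values)
        assert peak_a > 5 * floor and peak_b > 5 * floor
        # the Gaussian stack sees each bead only in its own plane
        disk = make_pupil_grid(cfg)
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")  # 1-um z-step is deliberately coarse here
            gauss_psf = compute_psf(disk, zs, cfg, crop_to_px=32)
        stack = image_phantom(ph, gauss_psf, "gaussian_stack").values
        plane_a, plane_b = stack[20], stack[40]
        assert plane_a[18:22, 8:12].max() > 10 * plane_a[18:22, 28:32].max()
        assert plane_b[18:22, 28:32].max() > 10 * plane_b[18:22, 8:12].max()

    def test_projection_equals_axially_weighted_plane_sum(self, cfg):
        # on sparse beads the Bessel frame is the axial-profile-weighted sum
        # of per-plane images
        ring = annulus_field(AnnularMaskSpec.from_hardware(cfg), cfg)
        zs = np.arange(-16.0, 16.001, 2.0)
        psf = compute_psf(ring, zs, cfg, crop_to_px=32)
        # beads inside the central part of the axial envelope, where the
        # lateral ring structure is nearly z-invariant
        ph = make_phantom(
            "beads", shape_um=(16, 16, 16), voxel_um=(2.0, 0.5, 0.5), n_beads=5,
            bead_diameter_um=1.0, seed=4,
        )
        proj = image_phantom(ph, psf, "bessel_projection").values
        from besselao.imaging import _resample_psf

        kernel = _resample_psf(psf, ph.voxel_um)
        from scipy.signal import fftconvolve

        weights = kernel.sum(axis=(1, 2))
        mid = ph.density.shape[0] // 2
        lateral = kernel.sum(axis=0)
        lateral /= lateral.sum()
        approx = np.zeros_like(proj)
        nzk = kernel.shape[0]
        for k, wgt in enumerate(weights):
            z_idx = mid - (k - nzk // 2)
            if 0 <= z_idx < ph.density.shape[0]:
                approx += wgt * fftconvolve(ph.density[z_idx], lateral, mode="same")
        rms = np.sqrt(np.mean((proj - approx) ** 2)) / proj.max()
        assert rms < 0.05

    def test_poisson_noise_reproducible_by_seed(self, gaussian_psf):
        ph = make_phantom("beads", shape_um=(4, 4, 4), voxel_um=(0.1, 0.1, 0.1), n_beads=2, seed=1)
        a = image_phantom(ph, gaussian_psf, "gaussian_stack", photon_budget=100, seed=9)
        b = image_phantom(ph, gaussian_psf, "gaussian_stack", photon_budget=100, seed=9)
        assert np.array_equal(a.values, b.values)


class TestDeconvolution:
    def _blurred_two_points(self):
        rng = np.random.default_rng(0)
        x = np.arange(128)
        kernel = np.exp(-((x - 64) ** 2) / (2 * 4.0**2))
        kernel2d = np.outer(kernel, kernel)
        kernel2d /= kernel2d.sum()
        scene = np.zeros((128, 128))
        # separation 1.2x the blur FWHM (~9.4 px)
        scene[64, 58] = 1.0
        scene[64, 69] = 1.0
        from scipy.signal import fftconvolve

        img = fftconvolve(scene, kernel2d, mode="same")
        return img, kernel2d

    def test_zero_iterations_is_identity(self):
        img, k = self._blurred_two_points()
        out = deconvolve(img, k, 0)
        assert np.array_equal(out, img)

    def test_flux_conserved(self):
        img, k = self._blurred_two_points()
        out = deconvolve(img, k, 15)
        assert out.sum() == pytest.approx(img.sum(), rel=1e-3)
        assert np.all(out >= 0)

    def test_two_point_contrast_deepens_monotonically(self):
        img, k = self._blurred_two_points()
        dips = []
        for it in range(1, 11):
            out = deconvolve(img, k, it)
            line = out[64]
            peaks = max(line[58], line[69])
            valley = line[58:70].min()
            dips.append(1 - valley / peaks)
        assert all(b >= a - 1e-9 for a, b in zip(dips, dips[1:]))
        assert dips[-1] > dips[0]


class TestSpineDetectability:
    def test_aberration_correction_recovers_spine_detections(self, cfg):
        # trefoil at 1 wave on the ring scatters energy into side lobes and
        # hides spines that the corrected (unaberrated) Bessel image shows
        ring = annulus_field(AnnularMaskSpec.from_hardware(cfg), cfg)
        zs = np.arange(-20.0, 20.001, 2.0)
        psf_good = compute_psf(ring, zs, cfg, crop_to_px=64)
        ring_ab = zernike_aberration(ring, (3, 3), 1.0)
        # the ring samples the full-pupil mode weakly; express it on the ring
        from besselao.zernike import zernike_eval

        rho = ring.na_radius() / 0.35
        w = 1.0 * zernike_eval(3, 3, rho, ring.azimuth())
        ring_ab = ring.copy_with(ring.values * np.exp(2j * np.pi * w))
        psf_bad = compute_psf(ring_ab, zs, cfg, crop_to_px=64)
        ph = make_phantom(
            "dendrites", shape_um=(30, 24, 24), voxel_um=(2.0, 0.2, 0.2),
            n_spines=12, seed=21,
        )
        img_good = image_phantom(ph, psf_good, "bessel_projection")
        img_bad = image_phantom(ph, psf_bad, "bessel_projection")
        n_good = sum(detect_spines(img_good, ph))
        n_bad = sum(detect_spines(img_bad, ph))
        assert n_good > n_bad
        assert n_good >= 0.5 * 12
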