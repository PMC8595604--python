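"""Annular mask geometry, axicon pattern, and the focal-pattern pipeline."""

import numpy as np
import pytest

from besselao.bessel import (
    AnnularMaskSpec,
    annulus_amplitude,
    apply_annulus,
    binary_axicon,
    compute_focal_correction,
    derive_annulus_na,
    ideal_bessel_pattern,
    random_smooth_aberration,
    simulate_bessel_peak,
    validate_focal_pattern,
)
from besselao.pupil import FocalPattern
from besselao.zernike import ZernikeCoefficients, zernike_surface


class TestBinaryAxicon:
    def test_two_values_with_half_duty_cycle(self):
        pat = binary_axicon(22.5, 1152)
        assert set(np.unique(pat)) == {0.0, np.pi}
        frac = np.mean(pat == np.pi)
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_fft_concentrates_energy_in_annulus_at_grating_frequency(self):
        n = 512
        pat = binary_axicon(16.0, n)
        field = np.fft.fftshift(np.fft.fft2(np.exp(1j * pat)))
        inten = np.abs(field) ** 2
        ax = np.fft.fftshift(np.fft.fftfreq(n))
        rr = np.hypot(ax[None, :], ax[:, None])
        # exclude the undiffracted DC spot, then ask where the rest lives
        off_axis = rr > 1.0 / 64
        ring = off_axis & (np.abs(rr - 1.0 / 16.0) < 1.0 / 64)
        assert inten[ring].sum() / inten[off_axis].sum() > 0.5

    def test_undersampled_period_rejected(self):
        with pytest.raises(ValueError):
            binary_axicon(3.0, 256)

    def test_infinite_period_degenerates_to_uniform_phase(self):
        pat = binary_axicon(1e9, 128)
        assert np.all(pat == 0.0)


class TestAnnulusGeometry:
    def test_relay_magnification_and_na_from_printed_hardware(self, cfg):
        # 1.015/1.2-mm mask through the x14/3 relay on an 8.4-mm pupil
        na_in, na_out = derive_annulus_na(1.015, 1.2, cfg)
        assert na_in == pytest.approx(1.05 * (1.015 / 2 * 14 / 3) / 8.4)
        assert na_in == pytest.approx(0.296, abs=0.001)
        assert na_out == pytest.approx(0.35, abs=0.001)

    def test_annulus_beyond_objective_na_rejected(self, cfg):
        with pytest.raises(ValueError):
            derive_annulus_na(1.015, 4.0, cfg)
        with pytest.raises(ValueError):
            AnnularMaskSpec.from_na(0.9, 1.2, cfg)

    def test_energy_ratio_is_area_ratio(self, cfg, disk, hardware_mask):
        # wide annulus: discretization error ~ 1 px / ring width
        wide = AnnularMaskSpec.from_na(0.3, 0.6, cfg)
        ann = apply_annulus(disk, wide)
        expected = (wide.na_outer**2 - wide.na_inner**2) / cfg.na_objective**2
        assert ann.energy / disk.energy == pytest.approx(expected, rel=0.03)
        # the thin hardware ring (~3 px wide) is area-faithful only through
        # the anti-aliased synthesis path
        from besselao.bessel import annulus_field

        soft = annulus_field(hardware_mask, cfg)
        area = np.sum(np.abs(soft.values))  # amplitude sum ~ transmitting area
        expected_hw = (hardware_mask.na_outer**2 - hardware_mask.na_inner**2) / cfg.na_objective**2
        assert area / np.sum(np.abs(disk.values)) == pytest.approx(expected_hw, rel=0.03)

    def test_apply_twice_equals_apply_once(self, disk, hardware_mask):
        once = apply_annulus(disk, hardware_mask)
        twice = apply_annulus(once, hardware_mask)
        assert np.allclose(twice.values, once.values)

    def test_phase_untouched_inside_ring(self, disk, hardware_mask):
        phase = zernike_surface(3, 3, disk)
        field = disk.copy_with(disk.values * np.exp(1j * phase))
        ann = apply_annulus(field, hardware_mask)
        band = annulus_amplitude(disk, hardware_mask) > 0.5
        assert np.allclose(np.angle(ann.values[band]), np.angle(field.values[band]))

    def test_empty_annulus_rejected(self, cfg, disk):
        with pytest.raises(ValueError):
            apply_annulus(disk, AnnularMaskSpec.from_na(0.4000, 0.4001, cfg))


class TestFocalCorrection:
    def test_zero_input_reproduces_ideal_bessel_pattern(self, cfg, hardware_mask):
        b = compute_focal_correction(None, hardware_mask, cfg, validate=False)
        ideal = ideal_bessel_pattern(hardware_mask, cfg)
        assert np.array_equal(b.pattern.phase, ideal.phase)

    def test_pure_defocus_input_equals_zero_input(self, cfg, disk, hardware_mask):
        # defocus is removed by construction (it would skew the axial profile)
        b0 = compute_focal_correction(None, hardware_mask, cfg, validate=False)
        bd = compute_focal_correction(
            0.7 * zernike_surface(2, 0, disk), hardware_mask, cfg, validate=False
        )
        # compare on the unit circle: wrapped phases can differ by 2*pi
        assert np.allclose(
            np.exp(1j * bd.pattern.phase), np.exp(1j * b0.pattern.phase), atol=1e-6
        )

    def test_deterministic_bit_identical(self, cfg, disk, hardware_mask):
        w = zernike_surface(3, 3, disk) + 0.3 * zernike_surface(2, -2, disk)
        p1 = compute_focal_correction(w, hardware_mask, cfg, validate=False).pattern.phase
        p2 = compute_focal_correction(w, hardware_mask, cfg, validate=False).pattern.phase
        assert np.array_equal(p1, p2)

    def test_trefoil_round_trip_validation(self, cfg, disk, hardware_mask):
        b = compute_focal_correction(zernike_surface(3, 3, disk), hardware_mask, cfg)
        v = b.validation
        assert v["phase_correlation"] > 0.9
        assert v["containment_ratio"] > 0.8
        assert v["centroid_offset_px"] < 1.0

    def test_tip_tilt_removal_keeps_annulus_centered(self, cfg, disk, hardware_mask):
        w = 1.0 * zernike_surface(1, 1, disk) + 0.8 * zernike_surface(1, -1, disk) + 0.5 * zernike_surface(2, 2, disk)
        b = compute_focal_correction(w, hardware_mask, cfg)
        assert b.validation["centroid_offset_px"] < 1.0
        assert b.edited[(1, 1)] == 0.0 and b.edited[(1, -1)] == 0.0

    def test_random_phase_pattern_gives_chance_containment(self, cfg, hardware_mask):
        rng = np.random.default_rng(0)
        n = cfg.padded_n
        pat = FocalPattern(phase=rng.uniform(-np.pi, np.pi, (n, n)), pitch_um=cfg.focal_pitch_um)
        rep = validate_focal_pattern(pat, hardware_mask, None, cfg)
        # chance level: dilated annulus area over the padded plane area
        pad_na = 2 * cfg.na_per_px
        chance = (
            np.pi * ((hardware_mask.na_outer + pad_na) ** 2 - (hardware_mask.na_inner - pad_na) ** 2)
            / (2 * cfg.na_max * cfg.pupil_oversampling) ** 2
        )
        assert rep["containment"] == pytest.approx(chance, rel=0.2)
        assert rep["containment"] < 0.2 * rep["containment_ideal"]

    def test_fit_residual_warning_recorded_for_rough_wavefront(self, cfg, disk, hardware_mask):
        rng = np.random.default_rng(3)
        rough = rng.normal(0, 0.5, (cfg.grid_n, cfg.grid_n))
        with pytest.warns(UserWarning, match="residual"):
            b = compute_focal_correction(rough, hardware_mask, cfg, validate=False)
        assert b.validation["warnings"]


class TestEndToEndGain:
    def test_focal_correction_recovers_peak_for_m_ge_2_aberration(self, cfg, disk, hardware_mask):
        # ~1 wave of mixed astigmatism + trefoil: heavily degrades the ring,
        # focal correction restores >= 90% of the unaberrated peak
        w = ZernikeCoefficients({(2, 2): 1.0, (3, -3): 1.0}).surface(disk)
        ref = simulate_bessel_peak(cfg, hardware_mask)
        unc = simulate_bessel_peak(cfg, hardware_mask, w)
        cor = simulate_bessel_peak(cfg, hardware_mask, w, correction="focal")
        assert cor / ref >= 0.9
        assert cor > unc

    def test_focal_beats_pupil_correction_for_displaced_aberration(self, cfg, hardware_mask):
        ab = random_smooth_aberration(cfg, 1.0, rng=7)
        for d in (50.0, 150.0):
            pupil_ao = simulate_bessel_peak(
                cfg, hardware_mask, ab, correction="pupil", screen_displacement_mm=d
            )
            focal_ao = simulate_bessel_peak(
                cfg, hardware_mask, ab, correction="focal", screen_displacement_mm=d
            )
            assert focal_ao > pupil_ao
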