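"""dF/F0 arithmetic, selectivity testing, tuning fits, gOSI, session recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from besselao.tuning import (
    RoiTraceSet,
    RoiTruth,
    StimulusSchedule,
    analyze_session,
    ang,
    compute_dff,
    dominant_orientation,
    evoked_response,
    fit_tuning,
    generate_session,
    gosi,
    selectivity_test,
    tuning_model,
)

DIRS = np.arange(0.0, 360.0, 30.0)


@pytest.fixture(scope="module")
def schedule():
    return StimulusSchedule.bessel_mode(n_trials=10)


class TestDff:
    def test_constant_trace_gives_zero_dff(self, schedule):
        traces = RoiTraceSet(np.full((1, schedule.n_frames), 50.0), schedule)
        dff, ok = compute_dff(traces)
        assert ok[0]
        assert np.allclose(dff, 0.0)

    def test_step_to_120_percent_gives_dff_of_0p2(self, schedule):
        fpe = schedule.frames_per_epoch
        pre, grating, _ = schedule.epoch_frames()
        epoch = np.full(fpe, 100.0)
        epoch[grating] = 120.0
        traces = RoiTraceSet(np.tile(epoch, (1, schedule.n_epochs)), schedule)
        dff, _ = compute_dff(traces)
        assert np.allclose(dff[0, :, grating], 0.2)
        assert np.allclose(dff[0, :, pre], 0.0)

    def test_nonpositive_baseline_flags_roi(self, schedule):
        traces = RoiTraceSet(np.zeros((1, schedule.n_frames)), schedule)
        _, ok = compute_dff(traces)
        assert not ok[0]


class TestEvokedResponse:
    def test_zero_session_has_no_transients(self, schedule):
        dff = np.zeros((1, schedule.n_epochs, schedule.frames_per_epoch))
        ev = evoked_response(dff, schedule)
        assert np.allclose(ev["responses"], 0.0)
        assert not ev["responsive"][0]

    def test_single_direction_plateau_is_classified_responsive(self, schedule):
        dff = np.zeros((1, schedule.n_epochs, schedule.frames_per_epoch))
        _, grating, _ = schedule.epoch_frames()
        order = schedule.presentation_order()
        target_epochs = np.where(order == 3)[0]
        dff[0, target_epochs, grating] = 0.3
        ev = evoked_response(dff, schedule)  # 20% calcium threshold
        assert np.allclose(ev["responses"][0, 3], 0.3)
        assert ev["responsive"][0]
        assert ev["transients"][0, 3].all()
        assert not ev["transients"][0, 4].any()


class TestSelectivity:
    def test_identical_responses_not_selective(self):
        p, sel = selectivity_test(np.ones((12, 10)))
        assert not sel and p == 1.0

    def test_zero_variance_with_tuning_is_selective(self):
        r = np.ones((12, 5))
        r[4] = 3.0
        p, sel = selectivity_test(r)
        assert sel and p == 0.0

    def test_strong_tuning_detected(self, rng):
        r = rng.normal(0, 1, (12, 10))
        r[7] += 10.0  # one direction elevated by 10 pooled SDs
        p, sel = selectivity_test(r)
        assert sel and p < 1e-3

    def test_false_positive_rate_near_alpha_on_permuted_labels(self):
        # permuting direction labels of tuned data destroys the effect; the
        # ANOVA should then reject at ~ the nominal 5% rate
        rng = np.random.default_rng(7)
        base = tuning_model(DIRS, 0.1, 1.0, 0.5, 90.0, 30.0)
        rejections = 0
        n_perm = 500
        for _ in range(n_perm):
            r = base[:, None] + rng.normal(0, 1.0, (12, 10))
            flat = r.ravel()
            rng.shuffle(flat)
            _, sel = selectivity_test(flat.reshape(12, 10))
            rejections += sel
        assert rejections / n_perm == pytest.approx(0.05, abs=0.025)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            selectivity_test(np.ones((12, 1)))


class TestTuningFit:
    def test_noiseless_parameters_recovered_to_under_one_percent(self):
        r = tuning_model(DIRS, 0.1, 1.0, 0.5, 90.0, 30.0)
        fit = fit_tuning(r, DIRS)
        assert fit.theta_pref_deg == pytest.approx(90.0, abs=0.9)
        assert fit.sigma_deg == pytest.approx(30.0, rel=0.01)
        assert fit.r_pref == pytest.approx(1.0, rel=0.01)
        assert fit.r_oppo == pytest.approx(0.5, rel=0.01)
        assert fit.r_offset == pytest.approx(0.1, abs=0.01)

    def test_taller_peak_defines_preferred_direction(self):
        r = tuning_model(DIRS, 0.0, 0.4, 1.0, 45.0, 25.0)  # oppo taller
        fit = fit_tuning(r, DIRS)
        assert fit.r_pref >= fit.r_oppo
        assert fit.theta_pref_deg == pytest.approx(225.0, abs=1.0)

    def test_wrap_handling_near_zero_degrees(self):
        r = tuning_model(DIRS, 0.0, 1.0, 0.3, 350.0, 25.0)
        fit = fit_tuning(r, DIRS)
        err = abs(ang(fit.theta_pref_deg - 350.0))
        assert err < 2.0


class TestGosi:
    def test_analytic_cases_exact(self):
        single = np.zeros(12)
        single[5] = 2.0
        assert gosi(single, DIRS) == pytest.approx(1.0, abs=1e-12)
        assert gosi(np.ones(12), DIRS) == pytest.approx(0.0, abs=1e-12)
        pair180 = np.zeros(12)
        pair180[1] = pair180[7] = 1.0  # theta and theta+180
        assert gosi(pair180, DIRS) == pytest.approx(1.0, abs=1e-12)
        pair90 = np.zeros(12)
        pair90[1] = pair90[4] = 1.0  # theta and theta+90
        assert gosi(pair90, DIRS) == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_flagged_nan(self):
        assert np.isnan(gosi(np.zeros(12), DIRS))

    @settings(derandomize=True, max_examples=30)
    @given(
        scale=st.floats(0.1, 10.0),
        seed=st.integers(0, 10_000),
    )
    def test_scale_invariance(self, scale, seed):
        r = np.random.default_rng(seed).random(12)
        assert gosi(scale * r, DIRS) == pytest.approx(gosi(r, DIRS), abs=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000), frac=st.floats(0.0, 1.0))
    def test_adding_proportional_opposite_responses_preserves_gosi(self, seed, frac):
        r = np.zeros(12)
        r[:6] = np.random.default_rng(seed).random(6)
        mirrored = r + frac * np.roll(r, 6)  # e^{2i theta} has period 180 deg
        assert gosi(mirrored, DIRS) == pytest.approx(gosi(r, DIRS), abs=1e-9)

    def test_negative_means_floored_keeps_index_in_unit_interval(self):
        r = np.array([-0.5, 1.0] + [0.0] * 10)
        g = gosi(r, DIRS)
        assert 0.0 <= g <= 1.0 and g == pytest.approx(1.0)


class TestDominantOrientation:
    def test_delta_histogram_centers_on_the_single_value(self):
        out = dominant_orientation(np.full(40, 144.0))
        assert out["status"] == "ok"
        assert out["center_deg"] == pytest.approx(144.0, abs=7.5)  # within a bin

    def test_wrapped_gaussian_sample_recovers_center(self):
        rng = np.random.default_rng(2)
        sigma = 46.0 / 2.3548
        sample = np.mod(63.0 + rng.normal(0, sigma, 40), 180.0)
        out = dominant_orientation(sample)
        assert out["status"] == "ok"
        d = np.mod(out["center_deg"] - 63.0 + 90, 180) - 90
        assert abs(d) <= 10.0

    def test_uniform_orientations_have_no_dominant_peak(self):
        rng = np.random.default_rng(3)
        out = dominant_orientation(rng.uniform(0, 180, 200))
        assert out["status"] == "no_dominant_peak"

    def test_too_few_entries_rejected(self):
        with pytest.raises(ValueError):
            dominant_orientation(np.array([10.0, 20.0]))


class TestSessionGenerator:
    def test_fixed_seed_is_bit_identical(self, schedule):
        truths = [RoiTruth(), RoiTruth(theta_pref_deg=30.0)]
        a = generate_session(truths, schedule, seed=5)
        b = generate_session(truths, schedule, seed=5)
        assert np.array_equal(a.traces, b.traces)

    def test_zero_noise_zero_tuning_gives_flat_traces(self, schedule):
        truths = [RoiTruth(responsive=False)]
        ses = generate_session(truths, schedule, noise_sigma=0.0, seed=0)
        assert np.allclose(ses.traces, ses.traces[0, 0])

    def test_full_chain_recovers_responsive_fraction(self):
        # 91 ROIs, 58% truly responsive: the analysis chain's responsive
        # fraction lands within the binomial confidence band of the truth
        sched = StimulusSchedule.bessel_mode(n_trials=10)
        rng = np.random.default_rng(42)
        n_roi, frac = 91, 0.58
        responsive = rng.random(n_roi) < frac
        truths = [
            RoiTruth(
                theta_pref_deg=float(rng.uniform(0, 360)),
                r_pref=1.0,
                r_oppo=0.4,
                responsive=bool(resp),
            )
            for resp in responsive
        ]
        ses = generate_session(truths, sched, noise_sigma=0.03, seed=43)
        results = analyze_session(ses)
        est = np.mean([r["responsive"] for r in results])
        true_frac = responsive.mean()
        ci = 1.96 * np.sqrt(true_frac * (1 - true_frac) / n_roi)
        assert abs(est - true_frac) <= ci + 0.02

    def test_lower_snr_monotonically_degrades_detection_and_gosi(self):
        # the mechanism behind the with/without-AO contrast: same ground
        # truth, poorer SNR -> fewer transient-passing ROIs and lower gOSI
        sched = StimulusSchedule.bessel_mode(n_trials=10)
        rng = np.random.default_rng(0)
        truths = [
            RoiTruth(theta_pref_deg=float(rng.uniform(0, 360)), r_pref=0.5, r_oppo=0.2)
            for _ in range(40)
        ]
        frac_responsive = []
        median_gosi = []
        # lower signal amplitude at fixed noise emulates aberration-induced
        # signal loss (dF/F0 scales with excitation at the synapse)
        for gain in (1.0, 0.5, 0.25):
            scaled = [
                RoiTruth(
                    theta_pref_deg=t.theta_pref_deg,
                    r_pref=gain * t.r_pref,
                    r_oppo=gain * t.r_oppo,
                )
                for t in truths
            ]
            ses = generate_session(scaled, sched, noise_sigma=0.05, seed=11)
            results = analyze_session(ses)
            frac_responsive.append(np.mean([r["responsive"] for r in results]))
            gs = [r["gosi"] for r in results if np.isfinite(r.get("gosi", np.nan))]
            median_gosi.append(np.median(gs))
        assert frac_responsive[0] >= frac_responsive[1] >= frac_responsive[2]
        assert frac_responsive[0] > frac_responsive[2]
        assert median_gosi[0] >= median_gosi[1] >= median_gosi[2]
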