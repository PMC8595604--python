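"""Orientation-tuning statistics for drifting-grating imaging sessions.

Implements the standard analysis chain for visually evoked calcium or
glutamate signals: per-trial dF/F0 against the pre-stimulus blank, evoked
responses averaged over the grating epoch, one-way-ANOVA orientation
selectivity, a bimodal (two-peaked) Gaussian tuning-curve fit

    R(theta) = R_offset + R_pref * exp(-ang(theta - theta_pref)^2 / 2 sigma^2)
                        + R_oppo * exp(-ang(theta - theta_pref + 180)^2 / 2 sigma^2)

with ang(.) the angular difference wrapped to (-180, 180], and the global
orientation-selectivity index

    gOSI = | sum_k R(theta_k) exp(2i theta_k) | / sum_k R(theta_k)

(the modulus is taken so the index lands in [0, 1]; negative mean responses
are floored at zero first).  A session generator with known ground truth
supports parameter-recovery and calibration studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

CALCIUM_TRANSIENT_THRESHOLD = 0.20  # dF/F0 above which a calcium transient is scored
GLUTAMATE_TRANSIENT_THRESHOLD = 0.10  # default glutamate threshold (0.05 also in use)


@dataclass
class StimulusSchedule:
    """Trial-structured drifting-grating protocol.

    Defaults follow the two acquisition modes: Gaussian scanning presents
    (2 s blank, 4 s grating, 2 s blank) at 3.3 Hz; Bessel scanning presents
    (4 s blank, 6 s grating, 2 s blank) at 1.5 Hz.  Twelve directions,
    0-330 degrees in 30-degree steps, pseudorandomly ordered per trial block.
    """

    directions_deg: tuple[float, ...] = tuple(float(d) for d in range(0, 360, 30))
    n_trials: int = 10
    blank_pre_s: float = 4.0
    grating_s: float = 6.0
    blank_post_s: float = 2.0
    frame_rate_hz: float = 1.5
    seed: int = 0

    @classmethod
    def gaussian_mode(cls, n_trials: int = 10, seed: int = 0) -> "StimulusSchedule":
        return cls(blank_pre_s=2.0, grating_s=4.0, blank_post_s=2.0, frame_rate_hz=3.3, n_trials=n_trials, seed=seed)

    @classmethod
    def bessel_mode(cls, n_trials: int = 10, seed: int = 0) -> "StimulusSchedule":
        return cls(blank_pre_s=4.0, grating_s=6.0, blank_post_s=2.0, frame_rate_hz=1.5, n_trials=n_trials, seed=seed)

    @property
    def epoch_s(self) -> float:
        return self.blank_pre_s + self.grating_s + self.blank_post_s

    @property
    def frames_per_epoch(self) -> int:
        return int(round(self.epoch_s * self.frame_rate_hz))

    @property
    def n_epochs(self) -> int:
        return len(self.directions_deg) * self.n_trials

    @property
    def n_frames(self) -> int:
        return self.frames_per_epoch * self.n_epochs

    def epoch_frames(self) -> tuple[slice, slice, slice]:
        """(blank_pre, grating, blank_post) frame slices within one epoch."""
        b = int(round(self.blank_pre_s * self.frame_rate_hz))
        g = int(round(self.grating_s * self.frame_rate_hz))
        return slice(0, b), slice(b, b + g), slice(b + g, self.frames_per_epoch)

    def presentation_order(self) -> np.ndarray:
        """Direction index per epoch: each trial block is a seeded shuffle."""
        rng = np.random.default_rng(self.seed)
        order = []
        for _ in range(self.n_trials):
            order.append(rng.permutation(len(self.directions_deg)))
        return np.concatenate(order)


@dataclass
class RoiTraceSet:
    """Per-ROI fluorescence time series aligned to a schedule."""

    traces: np.ndarray  # (n_roi, n_frames), raw fluorescence >= 0
    schedule: StimulusSchedule
    roi_info: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if abs(self.traces.shape[1] - self.schedule.n_frames) > 1:
            raise ValueError(
                f"trace length {self.traces.shape[1]} does not match schedule "
                f"({self.schedule.n_frames} frames)"
            )


@dataclass
class TuningFit:
    r_offset: float
    r_pref: float
    r_oppo: float
    theta_pref_deg: float
    sigma_deg: float
    residual: float
    p_value: float = np.nan
    gosi: float = np.nan
    success: bool = True


def ang(delta_deg: np.ndarray | float) -> np.ndarray | float:
    """Angular difference wrapped to (-180, 180] degrees."""
    return -(np.mod(-np.asarray(delta_deg, dtype=float) + 180.0, 360.0) - 180.0)


def tuning_model(theta_deg, r_offset, r_pref, r_oppo, theta_pref_deg, sigma_deg):
    """Bimodal Gaussian tuning curve (see module docstring)."""
    d1 = ang(np.asarray(theta_deg) - theta_pref_deg)
    d2 = ang(np.asarray(theta_deg) - theta_pref_deg + 180.0)
    return (
        r_offset
        + r_pref * np.exp(-np.square(d1) / (2 * sigma_deg**2))
        + r_oppo * np.exp(-np.square(d2) / (2 * sigma_deg**2))
    )


# ---------------------------------------------------------------------------
# dF/F0 and evoked responses


def compute_dff(traces: RoiTraceSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial dF/F0: baseline F0 is the mean over that epoch's pre-stimulus
    blank.

    Returns ``(dff, ok)`` where ``dff`` has shape (n_roi, n_epochs,
    frames_per_epoch) and ``ok`` flags ROIs whose baselines are all positive
    (ROIs with any F0 <= 0 are excluded from analysis).
    """
    sched = traces.schedule
    n_roi = traces.traces.shape[0]
    fpe = sched.frames_per_epoch
    usable = sched.n_epochs * fpe
    arr = traces.traces[:, :usable].reshape(n_roi, sched.n_epochs, fpe)
    pre, _, _ = sched.epoch_frames()
    f0 = arr[:, :, pre].mean(axis=2, keepdims=True)
    ok = (f0[:, :, 0] > 0).all(axis=1)
    safe_f0 = np.where(f0 > 0, f0, np.nan)
    dff = (arr - safe_f0) / safe_f0
    return dff, ok


def evoked_response(
    dff: np.ndarray,
    schedule: StimulusSchedule,
    *,
    transient_threshold: float = CALCIUM_TRANSIENT_THRESHOLD,
) -> dict:
    """Trial-resolved evoked responses R(theta).

    R is the mean dF/F0 over the grating epoch of each trial.  Returns a
    dict with ``responses`` (n_roi, n_directions, n_trials), ``directions``,
    ``transients`` (same shape, bool: R exceeds the transient threshold) and
    ``responsive`` (n_roi bool: any transient in any trial).
    """
    _, grating, _ = schedule.epoch_frames()
    per_epoch = np.nanmean(dff[:, :, grating], axis=2)  # (n_roi, n_epochs)
    order = schedule.presentation_order()
    n_dir = len(schedule.directions_deg)
    n_roi = dff.shape[0]
    responses = np.full((n_roi, n_dir, schedule.n_trials), np.nan)
    counts = np.zeros(n_dir, dtype=int)
    for epoch, d in enumerate(order):
        responses[:, d, counts[d]] = per_epoch[:, epoch]
        counts[d] += 1
    if not (counts == schedule.n_trials).all():
        import warnings

        warnings.warn("unbalanced design: unequal trial counts per direction", stacklevel=2)
    transients = responses > transient_threshold
    return {
        "responses": responses,
        "directions_deg": np.asarray(schedule.directions_deg),
        "transients": transients,
        "responsive": transients.any(axis=(1, 2)),
    }


def selectivity_test(responses: np.ndarray, alpha: float = 0.05) -> tuple[float, bool]:
    """One-way ANOVA across directions: is the ROI orientation-selective?

    ``responses`` is (n_directions, n_trials).  Degenerate zero-variance
    inputs: identical values everywhere -> not selective (p = 1); zero
    within-group but nonzero between-group variance -> selective (p = 0).
    """
    responses = np.asarray(responses, dtype=float)
    groups = [responses[d][np.isfinite(responses[d])] for d in range(responses.shape[0])]
    if any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 trials per direction")
    within = sum(np.var(g) for g in groups)
    between = np.var([g.mean() for g in groups])
    if within == 0:
        p = 1.0 if between == 0 else 0.0
        return p, p < alpha
    _, p = stats.f_oneway(*groups)
    return float(p), bool(p < alpha)


# ---------------------------------------------------------------------------
# Tuning fit and indices


def fit_tuning(
    mean_responses: np.ndarray,
    directions_deg: np.ndarray | None = None,
) -> TuningFit:
    """Least-squares bimodal-Gaussian fit of per-direction mean responses.

    The fit is multi-started with theta_pref at every stimulus direction;
    the lowest-residual solution wins (ties broken toward smaller sigma).
    """
    mean_responses = np.asarray(mean_responses, dtype=float)
    if directions_deg is None:
        directions_deg = np.arange(0.0, 360.0, 360.0 / len(mean_responses))
    directions_deg = np.asarray(directions_deg, dtype=float)

    lo = [-np.inf, 0.0, 0.0, -360.0, 5.0]
    hi = [np.inf, np.inf, np.inf, 720.0, 180.0]
    best: TuningFit | None = None
    span = float(mean_responses.max() - mean_responses.min())
    for theta0 in directions_deg:
        p0 = [
            float(mean_responses.min()),
            max(span, 1e-6),
            max(span / 2, 1e-6),
            float(theta0),
            30.0,
        ]
        try:
            popt, _ = optimize.curve_fit(
                tuning_model, directions_deg, mean_responses, p0=p0, bounds=(lo, hi), maxfev=2000
            )
        except RuntimeError:
            continue
        resid = float(np.sum((tuning_model(directions_deg, *popt) - mean_responses) ** 2))
        cand = TuningFit(
            r_offset=float(popt[0]),
            r_pref=float(popt[1]),
            r_oppo=float(popt[2]),
            theta_pref_deg=float(np.mod(popt[3], 360.0)),
            sigma_deg=float(popt[4]),
            residual=resid,
        )
        if (
            best is None
            or resid < best.residual * (1 - 1e-9)
            or (abs(resid - best.residual) <= best.residual * 1e-9 and cand.sigma_deg < best.sigma_deg)
        ):
            best = cand
    if best is None:
        return TuningFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.inf, success=False)
    if best.r_oppo > best.r_pref:
        # canonical orientation: the taller peak defines theta_pref
        best = TuningFit(
            best.r_offset,
            best.r_oppo,
            best.r_pref,
            float(np.mod(best.theta_pref_deg + 180.0, 360.0)),
            best.sigma_deg,
            best.residual,
        )
    return best


def gosi(mean_responses: np.ndarray, directions_deg: np.ndarray | None = None) -> float:
    """Global orientation-selectivity index in [0, 1].

    Modulus of the 2-theta phasor average of per-direction responses;
    negative means are floored at zero before summation.  Returns NaN (and
    the caller should flag the ROI) when all responses are zero.
    """
    r = np.clip(np.asarray(mean_responses, dtype=float), 0.0, None)
    if directions_deg is None:
        directions_deg = np.arange(0.0, 360.0, 360.0 / len(r))
    total = r.sum()
    if total <= 0:
        return np.nan
    phasor = np.sum(r * np.exp(2j * np.deg2rad(np.asarray(directions_deg, dtype=float))))
    return float(np.abs(phasor) / total)


def dominant_orientation(
    preferred_deg: np.ndarray,
    *,
    bin_width_deg: float = 15.0,
    amplitude_criterion: float = 3.0,
) -> dict:
    """Wrapped-Gaussian fit to the histogram of preferred orientations.

    Orientations are folded to [0, 180).  Returns ``{"center_deg",
    "fwhm_deg", "amplitude", "status"}`` with status ``"ok"`` or
    ``"no_dominant_peak"``: a peak counts as dominant when its fitted
    amplitude exceeds ``amplitude_criterion`` times the counting-noise scale
    ``sqrt(mean bin count)``, so flat histograms with Poisson-level bumps
    are rejected.
    """
    preferred_deg = np.mod(np.asarray(preferred_deg, dtype=float), 180.0)
    if preferred_deg.size < 5:
        raise ValueError("need >= 5 preferred orientations")
    n_bins = max(4, int(round(180.0 / bin_width_deg)))
    counts, edges = np.histogram(preferred_deg, bins=n_bins, range=(0.0, 180.0))
    centers = 0.5 * (edges[:-1] + edges[1:])

    def wrapped(theta, base, amp, mu, sigma):
        d = np.mod(theta - mu + 90.0, 180.0) - 90.0
        return base + amp * np.exp(-np.square(d) / (2 * sigma**2))

    best = None
    for mu0 in centers:
        try:
            popt, _ = optimize.curve_fit(
                wrapped,
                centers,
                counts,
                p0=[counts.min(), max(counts.max() - counts.min(), 1e-6), mu0, 25.0],
                bounds=([0, 0, -180, bin_width_deg / 4], [np.inf, np.inf, 360, 180]),
                maxfev=2000,
            )
        except RuntimeError:
            continue
        resid = float(np.sum((wrapped(centers, *popt) - counts) ** 2))
        if best is None or resid < best[0]:
            best = (resid, popt)
    if best is None:
        return {"center_deg": np.nan, "fwhm_deg": np.nan, "amplitude": 0.0, "status": "no_dominant_peak"}
    resid, (base, amp, mu, sigma) = best
    noise = np.sqrt(max(counts.mean(), 1.0))
    fwhm = 2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma
    # a peak must be significant against counting noise AND localized: on a
    # 180-degree domain a near-flat fit can masquerade as a very wide bump
    localized = fwhm < 120.0
    status = "ok" if (amp > amplitude_criterion * noise and localized) else "no_dominant_peak"
    return {
        "center_deg": float(np.mod(mu, 180.0)),
        "fwhm_deg": float(fwhm),
        "amplitude": float(amp),
        "status": status,
    }


# ---------------------------------------------------------------------------
# Synthetic sessions


@dataclass
class RoiTruth:
    """Ground-truth tuning for one simulated ROI."""

    r_pref: float = 1.0
    r_oppo: float = 0.5
    r_offset: float = 0.0
    theta_pref_deg: float = 90.0
    sigma_deg: float = 30.0
    responsive: bool = True


def generate_session(
    truths: list[RoiTruth],
    schedule: StimulusSchedule,
    *,
    baseline: float = 100.0,
    noise_sigma: float = 0.05,
    trial_jitter: float = 0.0,
    tau_rise_s: float = 0.25,
    tau_decay_s: float = 1.0,
    seed: int = 0,
) -> RoiTraceSet:
    """Simulate raw fluorescence traces with known tuning.

    Each epoch's grating window carries a transient ``A * (1 - exp(-t/tau_rise))``
    that decays with ``tau_decay`` afterwards, where the amplitude ``A``
    follows the bimodal Gaussian tuning (plus optional per-trial Gaussian
    ``trial_jitter``).  Gaussian read noise with SD ``noise_sigma * baseline``
    is added to the raw trace.  Calcium indicators are emulated by the slow
    default time constants; pass ~(0.05, 0.15) s for fast glutamate sensors.
    """
    rng = np.random.default_rng(seed)
    n_roi = len(truths)
    fpe = schedule.frames_per_epoch
    t = np.arange(fpe) / schedule.frame_rate_hz
    pre, grating, _ = schedule.epoch_frames()
    t_on = pre.stop / schedule.frame_rate_hz
    t_off = grating.stop / schedule.frame_rate_hz
    kernel = np.zeros(fpe)
    rise = ~np.less(t, t_on) & np.less(t, t_off)
    kernel[rise] = 1.0 - np.exp(-(t[rise] - t_on) / tau_rise_s)
    after = ~np.less(t, t_off)
    k_off = 1.0 - np.exp(-(t_off - t_on) / tau_rise_s)
    kernel[after] = k_off * np.exp(-(t[after] - t_off) / tau_decay_s)

    order = schedule.presentation_order()
    dirs = np.asarray(schedule.directions_deg)
    traces = np.empty((n_roi, schedule.n_frames))
    for r, truth in enumerate(truths):
        rows = []
        for d in order:
            if truth.responsive:
                amp = tuning_model(
                    dirs[d], truth.r_offset, truth.r_pref, truth.r_oppo, truth.theta_pref_deg, truth.sigma_deg
                )
                if trial_jitter > 0:
                    amp = amp + rng.normal(0.0, trial_jitter)
            else:
                amp = 0.0
            rows.append(baseline * (1.0 + max(float(amp), 0.0) * kernel))
        trace = np.concatenate(rows)
        trace = trace + rng.normal(0.0, noise_sigma * baseline, trace.shape)
        traces[r] = np.clip(trace, 0.0, None)
    return RoiTraceSet(traces=traces, schedule=schedule, roi_info=[vars(tr) for tr in truths])


def analyze_session(
    traces: RoiTraceSet,
    *,
    transient_threshold: float = CALCIUM_TRANSIENT_THRESHOLD,
    alpha: float = 0.05,
) -> list[dict]:
    """Run the full chain on a session: dF/F0 -> evoked R -> ANOVA ->
    (for selective ROIs) tuning fit and gOSI.  Returns one dict per ROI."""
    dff, ok = compute_dff(traces)
    ev = evoked_response(dff, traces.schedule, transient_threshold=transient_threshold)
    out = []
    for r in range(dff.shape[0]):
        rec: dict = {"roi": r, "baseline_ok": bool(ok[r])}
        if not ok[r]:
            rec.update({"responsive": False, "selective": False})
            out.append(rec)
            continue
        resp = ev["responses"][r]
        rec["responsive"] = bool(ev["responsive"][r])
        p, selective = selectivity_test(resp, alpha=alpha)
        rec["p_value"] = p
        rec["selective"] = selective
        mean_r = np.nanmean(resp, axis=1)
        rec["gosi"] = gosi(mean_r, ev["directions_deg"])
        if selective:
            fit = fit_tuning(mean_r, ev["directions_deg"])
            fit.p_value = p
            fit.gosi = rec["gosi"]
            rec["fit"] = fit
        out.append(rec)
    return out
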