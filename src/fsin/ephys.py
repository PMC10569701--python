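"""Electrophysiology trace analysis.

Implements the analyses applied to current-clamp and voltage-clamp recordings
of fast-spiking interneurons:

* AP detection (height >= -10 mV, prominence >= 20 mV, >= 2 ms separation) and
  AP waveform features -- threshold at 5% of the maximal rise slope, onset
  rapidity as the phase-plane slope around the 40 mV/ms crossing, rise/fall
  speeds as linear fits over the 30-70% threshold-to-peak span, half-width at
  half height between threshold and peak.
* Passive membrane features from hyperpolarizing steps and the four-criterion
  fast-spiking classification.
* Na+ current analysis: P/n capacitive/leak artifact subtraction, Boltzmann
  activation/inactivation fits with an R² > 0.85 acceptance gate, exponential
  activation/inactivation/recovery time constants.
* Unitary synaptic event analysis: EPSP features from averaged paired
  recordings, and per-event PSC latency/amplitude/rise time with failure
  exclusion and the < 2.5 ms monosynaptic window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import curve_fit
from scipy.signal import butter, filtfilt, find_peaks, savgol_filter
from scipy.stats import gaussian_kde

from .cable import epsp_metrics, _cross_time, _first_cross
from .traceio import Trace

# -- detection constants (printed analysis rules) ---------------------------
AP_MIN_HEIGHT = -10.0       # mV
AP_MIN_PROMINENCE = 20.0    # mV
AP_MIN_SEPARATION = 2.0     # ms
THRESHOLD_SLOPE_FRAC = 0.05
RAPIDITY_PHASE_LEVEL = 40.0       # mV/ms
RAPIDITY_WINDOW = (-0.006, 0.012)  # ms around the phase-plane crossing
SPEED_SPAN = (0.3, 0.7)            # fraction of threshold-to-peak span
R2_MIN = 0.85
MONOSYNAPTIC_MAX_LATENCY = 2.5     # ms


@dataclass
class APFeatures:
    threshold: float        # mV
    onset_rapidity: float   # 1/ms (NaN if phase plane never reaches 40 mV/ms)
    rise_speed: float       # mV/ms
    fall_speed: float       # mV/ms (negative)
    peak: float             # mV
    half_width: float       # ms


@dataclass
class BoltzmannFit:
    v_half: float
    slope_factor: float
    g_max: float
    r_squared: float

    @property
    def accepted(self) -> bool:
        """Fit-quality gate: only fits with R² > 0.85 are accepted."""
        return self.r_squared > R2_MIN


@dataclass
class EventRecord:
    """One unitary synaptic event referenced to a presynaptic AP peak."""

    onset_latency: float       # ms (NaN for failures)
    amplitude: float           # pA or mV, signed as recorded
    rise_time_10_90: float     # ms
    failure: bool

    @property
    def monosynaptic(self) -> bool:
        return (not self.failure) and self.onset_latency < MONOSYNAPTIC_MAX_LATENCY


@dataclass(frozen=True)
class FSINCriteria:
    """Fast-spiking classification thresholds (all strict inequalities)."""

    tau_m_max: float = 20.0        # ms
    fi_slope_min: float = 0.2      # Hz/pA
    rin_max: float = 200.0         # MΩ
    upstroke_downstroke_max: float = 1.7


# ---------------------------------------------------------------------------
# AP detection and waveform analysis
# ---------------------------------------------------------------------------

def detect_aps(trace: Trace) -> np.ndarray:
    """AP peak times: peaks >= -10 mV, prominence >= 20 mV, separation >= 2 ms.

    Within any cluster of peaks closer than 2 ms the higher peak wins.
    """
    distance = max(1, int(round(AP_MIN_SEPARATION / trace.dt)))
    idx, _ = find_peaks(trace.y, height=AP_MIN_HEIGHT,
                        prominence=AP_MIN_PROMINENCE, distance=distance)
    return trace.t0 + idx * trace.dt


def ap_waveform_features(trace: Trace, peak_time: float,
                         window_pre: float = 10.0, window_post: float = 5.0,
                         target_dt: float = 0.002,
                         smooth_window: float = 0.02) -> APFeatures:
    """Waveform features of the AP peaking at ``peak_time``.

    If the trace is sampled coarser than ``target_dt`` (2 µs), the analysis
    window is resampled with a cubic spline, which is logged via a warning;
    onset rapidity needs 2 µs resolution to resolve its 6-12 µs fit window.
    Before differentiation the waveform is smoothed with a cubic
    Savitzky-Golay filter over ``smooth_window`` ms (0 disables it); the
    window is short relative to AP curvature, so noiseless features are
    preserved while derivative noise is suppressed.
    """
    seg = trace.window(peak_time - window_pre, peak_time + window_post)
    t, y, dt = seg.t, seg.y, seg.dt
    if dt > target_dt * 1.001:
        warnings.warn(
            f"resampling trace from dt={dt} to {target_dt} ms for AP analysis",
            stacklevel=2)
        cs = CubicSpline(t, y)
        t = np.arange(t[0], t[-1], target_dt)
        y = cs(t)
        dt = target_dt
    y_raw = y
    win = int(round(smooth_window / dt)) | 1  # odd
    if win >= 5:
        y = savgol_filter(y, win, 3)
        sigma_hf = 1.4826 * float(np.median(np.abs(y_raw - y)))
    else:
        sigma_hf = 0.0
    dvdt = np.gradient(y, dt)
    i_pk = int(np.argmin(np.abs(t - peak_time)))
    lo, hi = max(i_pk - int(0.5 / dt), 0), min(i_pk + int(0.5 / dt), y.size - 1)
    i_pk = lo + int(np.argmax(y_raw[lo:hi + 1]))
    peak = _peak_estimate(t, y_raw, i_pk, lo, hi, dt, sigma_hf)

    i_smax = int(np.argmax(dvdt[:i_pk + 1]))
    s_max = float(dvdt[i_smax])
    thr_level = THRESHOLD_SLOPE_FRAC * s_max
    # walk backward from the maximal-slope point to the last sub-5% sample,
    # so baseline derivative noise ahead of the AP cannot trigger the rule
    i_thr = _last_below_before(dvdt, i_smax, thr_level)
    if i_thr is None:
        raise ValueError("could not locate AP threshold (no rising phase)")
    threshold = float(np.interp(thr_level, dvdt[i_thr:i_thr + 2],
                                y[i_thr:i_thr + 2])) if i_thr + 1 < y.size else float(y[i_thr])
    i_thr += 1  # first sample at/above the 5% level

    # onset rapidity: linear fit of dV/dt vs V around the 40 mV/ms crossing
    # (same backward search), undefined when the phase plane stays below it
    if s_max >= 1.2 * RAPIDITY_PHASE_LEVEL:
        i_rap = _last_below_before(dvdt, i_smax, RAPIDITY_PHASE_LEVEL)
    else:
        i_rap = None
    if i_rap is None:
        rapidity = float("nan")
    else:
        tc = t[i_rap] + dt * ((RAPIDITY_PHASE_LEVEL - dvdt[i_rap])
                              / (dvdt[i_rap + 1] - dvdt[i_rap] + 1e-300))
        sel = (t >= tc + RAPIDITY_WINDOW[0]) & (t <= tc + RAPIDITY_WINDOW[1])
        if sel.sum() >= 2:
            rapidity = float(np.polyfit(y[sel], dvdt[sel], 1)[0])
        else:
            rapidity = float("nan")

    span = peak - threshold
    lo_v, hi_v = threshold + SPEED_SPAN[0] * span, threshold + SPEED_SPAN[1] * span
    rise_speed = _span_slope(t, y, i_thr, i_pk, lo_v, hi_v)
    # repolarization: from peak to end
    fall_speed = _span_slope(t, y, i_pk, y.size - 1, hi_v, lo_v)

    half = threshold + 0.5 * span
    t_up = _first_cross(t, y, i_thr, i_pk, half)
    t_down = _first_cross_down(t, y, i_pk, y.size - 1, half)
    return APFeatures(threshold=threshold, onset_rapidity=rapidity,
                      rise_speed=rise_speed, fall_speed=fall_speed,
                      peak=peak, half_width=float(t_down - t_up))


def _first_above(x, i0, i1, level):
    idx = np.flatnonzero(x[i0:i1 + 1] >= level)
    return int(idx[0]) + i0 if idx.size else None


def _peak_estimate(t, y_raw, i_pk, lo, hi, dt, sigma_hf):
    """Peak voltage from the raw samples without max-statistic bias.

    The near-peak run (samples within a noise-scaled margin of the maximum)
    locates the top; a local quadratic fit supplies the peak for curved tops
    and the window mean for flat ones.
    """
    margin = max(0.05, 3.0 * sigma_hf)
    near = np.flatnonzero(y_raw[lo:hi + 1] >= y_raw[i_pk] - margin) + lo
    near = near[np.abs(near - i_pk) <= int(0.25 / dt)]
    center = int(np.median(near)) if near.size else i_pk
    w = max(2, int(round(0.02 / dt)))
    p0, p1 = max(center - w, 0), min(center + w, y_raw.size - 1)
    coef = np.polyfit(t[p0:p1 + 1] - t[center], y_raw[p0:p1 + 1], 2)
    vertex = -coef[1] / (2 * coef[0]) if coef[0] != 0 else np.inf
    if coef[0] < 0 and abs(vertex) <= (t[p1] - t[p0]) / 2:
        return float(np.polyval(coef, vertex))
    return float(np.mean(y_raw[p0:p1 + 1]))


def _last_below_before(x, i_ref, level):
    """Index of the last sample below ``level`` walking backward from i_ref."""
    below = np.flatnonzero(x[:i_ref + 1] < level)
    return int(below[-1]) if below.size else None


def _first_cross_down(t, y, i0, i1, level):
    for i in range(i0, i1):
        if y[i] >= level >= y[i + 1]:
            if y[i + 1] == y[i]:
                return t[i + 1]
            f = (level - y[i]) / (y[i + 1] - y[i])
            return t[i] + f * (t[i + 1] - t[i])
    return t[i1]


def _span_slope(t, y, i0, i1, v_from, v_to):
    """Slope of a linear fit of V(t) between two voltage levels."""
    lo, hi = min(v_from, v_to), max(v_from, v_to)
    sel = np.flatnonzero((y[i0:i1 + 1] >= lo) & (y[i0:i1 + 1] <= hi)) + i0
    if sel.size < 2:
        return float("nan")
    return float(np.polyfit(t[sel], y[sel], 1)[0])


def upstroke_downstroke_ratio(trace: Trace, peak_time: float) -> float:
    """max dV/dt divided by |min dV/dt| around the AP at ``peak_time``."""
    seg = trace.window(peak_time - 5.0, peak_time + 5.0)
    dvdt = np.gradient(seg.y, seg.dt)
    return float(dvdt.max() / abs(dvdt.min()))


def fi_slope(currents_pA, rates_Hz) -> float:
    """Least-squares slope of steady firing rate vs injected current (Hz/pA)."""
    return float(np.polyfit(np.asarray(currents_pA, float),
                            np.asarray(rates_Hz, float), 1)[0])


# ---------------------------------------------------------------------------
# Passive features and fast-spiking classification
# ---------------------------------------------------------------------------

def passive_features(trace: Trace, stim_onset: float, stim_dur: float,
                     amplitude_pA: float = -100.0) -> dict:
    """Passive features from a subthreshold hyperpolarizing step response.

    Returns deflection (baseline - steady state, mV), post-stimulus decay τ
    (ms), sag ratio ((peak deflection - steady deflection)/peak deflection),
    membrane time constant τ_m from the charging phase (ms), and input
    resistance R_in (MΩ).
    """
    if detect_aps(trace).size:
        raise ValueError("spiking during the step; passive analysis invalid")
    t, y = trace.t, trace.y
    i_on = trace.index_at(stim_onset)
    i_off = trace.index_at(stim_onset + stim_dur)
    baseline = float(np.mean(y[max(0, i_on - int(5.0 / trace.dt)):i_on]))
    steady = float(np.mean(y[i_off - max(1, int(0.1 * (i_off - i_on))):i_off]))
    deflection = baseline - steady
    i_min = i_on + int(np.argmin(y[i_on:i_off]))
    peak_deflection = baseline - float(y[i_min])
    sag_ratio = ((peak_deflection - deflection) / peak_deflection
                 if peak_deflection != 0 else float("nan"))

    # membrane time constant from the charging phase (before the sag peak)
    tau_m = _exp_tau(t[i_on:i_min + 1], y[i_on:i_min + 1], y_from=baseline,
                     y_to=float(y[i_min]))
    # decay back to baseline after stimulus end
    decay_tau = _exp_tau(t[i_off:], y[i_off:], y_from=float(y[i_off]),
                         y_to=baseline)
    r_in = abs(deflection / amplitude_pA) * 1e3  # mV/pA = GΩ -> MΩ
    return {"deflection": deflection, "decay_tau": decay_tau,
            "sag_ratio": sag_ratio, "tau_m": tau_m, "R_in": r_in}


def _exp_tau(t, y, y_from, y_to, hi=0.9, lo=0.2):
    """τ of an exponential relaxation from y_from toward y_to (log-linear fit)."""
    if len(t) < 4 or y_from == y_to:
        return float("nan")
    rel = (np.asarray(y) - y_to) / (y_from - y_to)   # 1 -> 0
    sel = np.flatnonzero((rel <= hi) & (rel >= lo))
    if sel.size < 3:
        sel = np.flatnonzero(rel > 0)[:10]
    if sel.size < 3:
        return float("nan")
    good = rel[sel] > 0
    slope = np.polyfit(np.asarray(t)[sel][good], np.log(rel[sel][good]), 1)[0]
    return float(-1.0 / slope) if slope < 0 else float("nan")


def classify_fsin(profile: dict, criteria: FSINCriteria = FSINCriteria()):
    """Fast-spiking classification from four measures (all must hold strictly).

    ``profile`` must contain ``tau_m`` (ms), ``fi_slope`` (Hz/pA), ``r_in``
    (MΩ) and ``upstroke_downstroke``.  Returns ``(is_fsin, report)`` where the
    report maps each criterion to its pass/fail.
    """
    for key in ("tau_m", "fi_slope", "r_in", "upstroke_downstroke"):
        if key not in profile or profile[key] is None:
            raise ValueError(f"missing measure {key!r} in profile")
    report = {
        "tau_m": profile["tau_m"] < criteria.tau_m_max,
        "fi_slope": profile["fi_slope"] > criteria.fi_slope_min,
        "r_in": profile["r_in"] < criteria.rin_max,
        "upstroke_downstroke":
            profile["upstroke_downstroke"] < criteria.upstroke_downstroke_max,
    }
    return all(report.values()), report


# ---------------------------------------------------------------------------
# Na+ current analysis
# ---------------------------------------------------------------------------

def pn_subtract(raw_sweeps, prepulse_sweeps, pulse_voltages, dt,
                prepulse_voltage: float = -40.0, holding: float = -90.0,
                lowpass_khz: float = 20.0):
    """P/n subtraction of linear capacitive/leak artifacts.

    The artifact template is the average of the prepulse responses (steps to
    ``prepulse_voltage``); it is scaled linearly by each sweep's step amplitude
    relative to the prepulse step amplitude and subtracted.  The corrected
    currents are then low-pass filtered at ``lowpass_khz`` (zero-phase 4th
    order Butterworth) when the sampling rate allows.
    """
    raw = np.atleast_2d(np.asarray(raw_sweeps, float))
    pre = np.atleast_2d(np.asarray(prepulse_sweeps, float))
    if raw.shape[1] != pre.shape[1]:
        raise ValueError("raw and prepulse sweeps have mismatched lengths")
    template = pre.mean(axis=0)
    scale = (np.asarray(pulse_voltages, float) - holding) / (prepulse_voltage - holding)
    corrected = raw - scale[:, None] * template[None, :]
    fs_khz = 1.0 / dt  # kHz
    if fs_khz > 2.0 * lowpass_khz:
        b, a = butter(4, lowpass_khz / (fs_khz / 2.0))
        corrected = filtfilt(b, a, corrected, axis=1)
    return corrected


def boltzmann_act(v, v_half, k, g_max=1.0):
    """Activation Boltzmann: G/G_max = 1 / (1 + exp((v_half - V)/k))."""
    return g_max / (1.0 + np.exp((v_half - np.asarray(v, float)) / k))


def boltzmann_inact(v, v_half, k, g_max=1.0):
    """Availability Boltzmann: 1 / (1 + exp((V - v_half)/k))."""
    return g_max / (1.0 + np.exp((np.asarray(v, float) - v_half) / k))


def _r_squared(y, y_fit):
    y = np.asarray(y, float)
    ss_res = float(np.sum((y - y_fit) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0


def fit_boltzmann(v, g_norm, kind: str) -> BoltzmannFit:
    """Fit a Boltzmann curve to normalized conductance/availability data."""
    fn = boltzmann_act if kind == "activation" else boltzmann_inact
    v = np.asarray(v, float)
    g = np.asarray(g_norm, float)
    v0 = float(np.interp(0.5, np.linspace(0, 1, v.size), np.sort(v)))
    try:
        popt, _ = curve_fit(fn, v, g, p0=[v0, 6.0, max(g.max(), 1e-9)],
                            maxfev=20000)
    except RuntimeError:
        return BoltzmannFit(float("nan"), float("nan"), float("nan"), 0.0)
    r2 = _r_squared(g, fn(v, *popt))
    return BoltzmannFit(float(popt[0]), float(popt[1]), float(popt[2]), r2)


def peak_amplitude(sweep, window, steady_frac: float = 0.05) -> float:
    """Peak inward current in ``window`` relative to the end-of-pulse steady state."""
    i0, i1 = window
    seg = np.asarray(sweep, float)[i0:i1]
    steady = float(np.mean(seg[-max(1, int(steady_frac * seg.size)):]))
    return float(seg.min() - steady)


def _na_pulse_model(t, a, tau_a, tau_i):
    return -a * (1.0 - np.exp(-t / tau_a)) * np.exp(-t / tau_i)


def fit_pulse_kinetics(sweep, window, dt):
    """Activation/inactivation τ from exponential fits to one pulse response.

    The rising phase and the decay are described by
    ``I(t) = -A (1 - exp(-t/τ_act)) exp(-t/τ_inact)``; both time constants are
    obtained from a joint least-squares fit.  Returns (τ_act, τ_inact, R²).
    """
    i0, i1 = window
    seg = np.asarray(sweep, float)[i0:i1]
    steady = float(np.mean(seg[-max(1, int(0.05 * seg.size)):]))
    y = seg - steady
    t = np.arange(y.size) * dt
    a0 = max(-y.min(), 1e-9)
    try:
        popt, _ = curve_fit(_na_pulse_model, t, y, p0=[a0, 0.1, 1.0],
                            bounds=([0, 1e-4, 1e-3], [np.inf, 50.0, 500.0]),
                            maxfev=20000)
    except RuntimeError:
        return float("nan"), float("nan"), 0.0
    r2 = _r_squared(y, _na_pulse_model(t, *popt))
    return float(popt[1]), float(popt[2]), r2


@dataclass
class SweepFamily:
    """A family of voltage-clamp sweeps sharing one pulse window.

    ``command_v`` is the variable voltage of the protocol: the test-pulse
    voltage for activation, the prepulse voltage for inactivation.
    """

    sweeps: np.ndarray
    dt: float
    command_v: np.ndarray
    pulse_window: tuple


@dataclass
class RecoveryFamily:
    """Paired-pulse recovery data at one recovery voltage."""

    recovery_v: float
    delays: np.ndarray          # ms between conditioning and test pulse
    amplitude_ratios: np.ndarray  # test/conditioning peak amplitude


@dataclass
class NaAnalysis:
    activation: BoltzmannFit
    inactivation: BoltzmannFit
    tau_activation: np.ndarray    # columns: V, τ_act, R²
    tau_inactivation: np.ndarray  # columns: V, τ_inact, R²
    tau_recovery: list            # (recovery_v, τ, R²) tuples


def na_curves_and_fits(activation: SweepFamily, inactivation: SweepFamily,
                       recovery, e_na: float = 64.0,
                       ljp_offset: float = 0.0) -> NaAnalysis:
    """Na+ current voltage dependence and kinetics from corrected sweep families.

    Activation: normalized conductance G = I_peak/(V - E_Na) vs pulse voltage,
    Boltzmann-fitted.  Inactivation: normalized availability vs prepulse
    voltage, Boltzmann-fitted.  τ_act/τ_inact per sweep from exponential fits
    to the pulse response; recovery τ per recovery voltage from
    ``1 - exp(-Δt/τ)`` fits to paired-pulse amplitude ratios.  The liquid
    junction potential ``ljp_offset`` is added to all command voltages at
    analysis time.  Fits carry their R²; callers exclude fits with R² <= 0.85
    via :attr:`BoltzmannFit.accepted`.
    """
    v_act = np.asarray(activation.command_v, float) + ljp_offset
    peaks = np.array([peak_amplitude(s, activation.pulse_window)
                      for s in activation.sweeps])
    g = peaks / (v_act - e_na)
    g_norm = g / g.max() if g.max() > 0 else g
    act_fit = fit_boltzmann(v_act, g_norm, "activation")

    v_in = np.asarray(inactivation.command_v, float) + ljp_offset
    pk_in = np.array([peak_amplitude(s, inactivation.pulse_window)
                      for s in inactivation.sweeps])
    avail = np.abs(pk_in) / np.abs(pk_in).max() if np.abs(pk_in).max() > 0 else pk_in
    inact_fit = fit_boltzmann(v_in, avail, "inactivation")

    taus = [fit_pulse_kinetics(s, activation.pulse_window, activation.dt)
            for s in activation.sweeps]
    tau_act = np.array([[v, ta, r2] for v, (ta, _ti, r2) in zip(v_act, taus)])
    tau_inact = np.array([[v, ti, r2] for v, (_ta, ti, r2) in zip(v_act, taus)])

    tau_rec = []
    for fam in recovery:
        d = np.asarray(fam.delays, float)
        r = np.asarray(fam.amplitude_ratios, float)
        try:
            popt, _ = curve_fit(lambda t, tau: 1.0 - np.exp(-t / tau), d, r,
                                p0=[max(d.mean(), 1.0)], maxfev=10000)
            r2 = _r_squared(r, 1.0 - np.exp(-d / popt[0]))
            tau_rec.append((float(fam.recovery_v) + ljp_offset, float(popt[0]), r2))
        except RuntimeError:
            tau_rec.append((float(fam.recovery_v) + ljp_offset, float("nan"), 0.0))
    return NaAnalysis(act_fit, inact_fit, tau_act, tau_inact, tau_rec)


# ---------------------------------------------------------------------------
# Unitary synaptic events
# ---------------------------------------------------------------------------

def connection_epsp_analysis(pre: Trace, post_traces, min_repeats: int = 5):
    """Unitary EPSP features from the average of repeated postsynaptic traces.

    The averaged trace is analyzed relative to the first presynaptic AP peak;
    onset latency is measured from that peak to EPSP onset.  Returns ``None``
    (no-connection verdict) when no response rises above the noise floor.
    """
    post_traces = list(post_traces)
    if len(post_traces) < min_repeats:
        raise ValueError(f"need >= {min_repeats} postsynaptic repetitions, "
                         f"got {len(post_traces)}")
    ap_times = detect_aps(pre)
    if ap_times.size == 0:
        raise ValueError("no presynaptic APs detected")
    avg = Trace(np.mean([tr.y for tr in post_traces], axis=0),
                post_traces[0].dt, post_traces[0].t0, site="post_avg",
                units=post_traces[0].units)
    return epsp_metrics(avg, stim_onset=float(ap_times[0]))


def psc_event_analysis(pre: Trace, post: Trace, polarity: int = -1,
                       search_window: float = 8.0, noise_mult: float = 4.0,
                       baseline_window: float = 2.0):
    """Per-AP unitary PSC events from a paired recording.

    For each presynaptic AP the postsynaptic current is searched over
    ``search_window`` ms; events are detected against the local pre-AP
    baseline, failures (no deflection beyond the noise floor) are flagged, and
    each detected event carries its onset latency (to the AP peak), amplitude
    and 10-90% rise time.  The monosynaptic flag marks latencies < 2.5 ms.
    """
    ap_times = detect_aps(pre)
    if ap_times.size == 0:
        raise ValueError("no presynaptic APs detected")
    y = post.y * polarity  # analyze as upward deflections
    events = []
    for ta in ap_times:
        i_a = post.index_at(ta)
        i_b = post.index_at(ta - baseline_window)
        i_end = min(post.index_at(ta + search_window), y.size - 1)
        base = y[i_b:i_a + 1]
        b_mean, b_sd = float(base.mean()), float(base.std())
        seg = y[i_a:i_end + 1]
        i_pk = int(np.argmax(seg)) + i_a
        amp = float(y[i_pk] - b_mean)
        thr_amp = max(noise_mult * b_sd, 1e-9)
        if amp <= thr_amp:
            events.append(EventRecord(float("nan"), 0.0, float("nan"), True))
            continue
        sub = Trace(y[i_b:i_end + 1], post.dt,
                    t0=post.t0 + i_b * post.dt, units=post.units)
        met = epsp_metrics(sub, stim_onset=float(ta),
                           baseline_window=baseline_window)
        if met is None:
            events.append(EventRecord(float("nan"), 0.0, float("nan"), True))
            continue
        events.append(EventRecord(met["onset_latency"],
                                  polarity * met["amplitude"],
                                  met["rise_time_10_90"], False))
    return events


def summarize_events(events) -> dict:
    """Per-connection summary: medians over non-failure events, failure count,
    monosynaptic subset medians and the latency distribution mode (KDE)."""
    ok = [e for e in events if not e.failure]
    mono = [e for e in ok if e.monosynaptic]
    lat = np.array([e.onset_latency for e in ok])
    out = {
        "n_events": len(events),
        "n_failures": sum(e.failure for e in events),
        "n_monosynaptic": len(mono),
        "median_latency": float(np.median(lat)) if ok else float("nan"),
        "median_amplitude": float(np.median([e.amplitude for e in ok])) if ok else float("nan"),
        "median_rise_time": float(np.median([e.rise_time_10_90 for e in ok])) if ok else float("nan"),
        "median_latency_monosynaptic":
            float(np.median([e.onset_latency for e in mono])) if mono else float("nan"),
    }
    if len(ok) >= 5 and np.ptp(lat) > 1e-6:
        kde = gaussian_kde(lat)
        grid = np.linspace(lat.min(), lat.max(), 512)
        out["latency_mode"] = float(grid[np.argmax(kde(grid))])
    else:
        out["latency_mode"] = out["median_latency"]
    return out
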