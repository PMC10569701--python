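"""Trace-analysis operations against their synthetic generators and the
printed detection/classification rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fsin.ephys import (BoltzmannFit, FSINCriteria, SweepFamily,
                        ap_waveform_features, boltzmann_act, boltzmann_inact,
                        classify_fsin, connection_epsp_analysis, detect_aps,
                        fit_boltzmann, na_curves_and_fits, passive_features,
                        pn_subtract, psc_event_analysis, summarize_events)
from fsin.synth import (APSpec, ArtifactSpec, EventSpec, NaTruth, TrainSpec,
                        gen_ap_trace, gen_connection_traces, gen_na_sweeps)
from fsin.traceio import Trace


def triangle_trace(peaks, dt=0.01, base=-65.0, width=1.0, duration=None):
    """Triangular spikes of given (time, height) pairs on a flat baseline."""
    if duration is None:
        duration = max(t for t, _ in peaks) + 10.0
    t = np.arange(0.0, duration, dt)
    y = np.full(t.size, base)
    for tp, h in peaks:
        rise = (t >= tp - width) & (t <= tp)
        fall = (t > tp) & (t <= tp + width)
        y[rise] = base + (h - base) * (1 - (tp - t[rise]) / width)
        y[fall] = base + (h - base) * (1 - (t[fall] - tp) / width)
    return Trace(y, dt, units="mV")


class TestDetectAPs:
    def test_single_suprathreshold_peak(self):
        assert detect_aps(triangle_trace([(20.0, 25.0)])).size == 1

    def test_low_peak_rejected_by_height_rule(self):
        # prominent (50 mV) but peaking below -10 mV
        assert detect_aps(triangle_trace([(20.0, -15.0)])).size == 0

    def test_close_peaks_collapsed_by_separation_rule(self):
        tr = triangle_trace([(20.0, 20.0), (21.0, 25.0)], width=0.45)
        assert detect_aps(tr).size == 1

    def test_low_prominence_rejected(self):
        t = np.arange(0, 50, 0.01)
        y = -5.0 + 10.0 * np.sin(2 * np.pi * t / 10.0)  # 20 mV swing → prom < 20...
        # use a small bump riding on a depolarized plateau
        y = np.full(t.size, -12.0)
        bump = (t >= 20) & (t <= 22)
        y[bump] += 15.0 * (1 - np.abs(t[bump] - 21.0))
        assert detect_aps(Trace(y, 0.01, units="mV")).size == 0

    def test_dc_offset_invariance(self):
        tr = triangle_trace([(20.0, 25.0), (30.0, 28.0)])
        shifted = Trace(tr.y + 5.0, tr.dt, units="mV")
        assert detect_aps(tr).size == detect_aps(shifted).size


class TestAPWaveform:
    SPEC = APSpec(threshold=-42.2, onset_rapidity=41.9, rise_speed=412.0,
                  fall_speed=-191.0, peak=30.0, half_width=0.5)

    def test_exact_recovery_noiseless(self):
        tr, _ = gen_ap_trace(self.SPEC, times=[20.0], dt=0.002)
        f = ap_waveform_features(tr, detect_aps(tr)[0])
        assert f.threshold == pytest.approx(-42.2, abs=0.05)
        assert f.onset_rapidity == pytest.approx(41.9, rel=0.01)
        assert f.rise_speed == pytest.approx(412.0, rel=0.005)
        assert f.fall_speed == pytest.approx(-191.0, rel=0.005)
        assert f.peak == pytest.approx(30.0, abs=0.01)
        assert f.half_width == pytest.approx(0.5, abs=0.005)

    def test_time_rescaling_halves_speeds_not_voltages(self):
        """Dimensional analysis: stretching time by 2 halves every slope-based
        feature and leaves voltage-based features unchanged."""
        tr, _ = gen_ap_trace(self.SPEC, times=[20.0], dt=0.002)
        slow = Trace(tr.y, tr.dt * 2.0, units="mV")
        f = ap_waveform_features(slow, detect_aps(slow)[0])
        assert f.rise_speed == pytest.approx(412.0 / 2, rel=0.005)
        assert f.fall_speed == pytest.approx(-191.0 / 2, rel=0.005)
        assert f.onset_rapidity == pytest.approx(41.9 / 2, rel=0.01)
        assert f.threshold == pytest.approx(-42.2, abs=0.05)
        assert f.peak == pytest.approx(30.0, abs=0.01)
        assert f.half_width == pytest.approx(1.0, abs=0.01)

    def test_dc_offset_shifts_voltages_only(self):
        tr, _ = gen_ap_trace(self.SPEC, times=[20.0], dt=0.002)
        up = Trace(tr.y + 4.0, tr.dt, units="mV")
        f0 = ap_waveform_features(tr, detect_aps(tr)[0])
        f1 = ap_waveform_features(up, detect_aps(up)[0])
        assert f1.threshold == pytest.approx(f0.threshold + 4.0, abs=0.05)
        assert f1.rise_speed == pytest.approx(f0.rise_speed, rel=0.005)

    def test_rapidity_flagged_when_phase_plane_too_slow(self):
        tr = triangle_trace([(20.0, 25.0)], width=5.0)  # max slope 18 mV/ms
        f = ap_waveform_features(tr, 20.0)
        assert np.isnan(f.onset_rapidity)


class TestPassiveFeatures:
    def rc_trace(self, R_MOhm=100.0, tau=10.0, dt=0.05, I_pA=-100.0,
                 sag_amp=0.0, sag_tau=40.0):
        t = np.arange(0.0, 300.0, dt)
        y = np.full(t.size, -70.0)
        on, off = 50.0, 150.0
        step = (t >= on) & (t < off)
        defl = R_MOhm * I_pA * 1e-3
        tl = t[step] - on
        y[step] = -70.0 + defl * (1 - np.exp(-tl / tau))
        if sag_amp:
            y[step] -= defl * sag_amp * (1 - np.exp(-tl / sag_tau))
        v_end = y[t < off][-1]
        after = t >= off
        y[after] = -70.0 + (v_end + 70.0) * np.exp(-(t[after] - off) / tau)
        return Trace(y, dt, units="mV")

    def test_ohmic_deflection_and_rin(self):
        pf = passive_features(self.rc_trace(), 50.0, 100.0, -100.0)
        assert pf["deflection"] == pytest.approx(10.0, rel=0.01)
        assert pf["R_in"] == pytest.approx(100.0, rel=0.01)
        assert pf["sag_ratio"] == pytest.approx(0.0, abs=0.02)

    def test_decay_tau_recovery(self):
        pf = passive_features(self.rc_trace(tau=12.0), 50.0, 100.0, -100.0)
        assert pf["decay_tau"] == pytest.approx(12.0, rel=0.01)
        assert pf["tau_m"] == pytest.approx(12.0, rel=0.05)

    def test_sag_measured(self):
        tr = self.rc_trace(sag_amp=0.15)
        pf = passive_features(tr, 50.0, 100.0, -100.0)
        # oracle straight off the constructed waveform
        base = tr.y[tr.index_at(49.0)]
        steady = tr.y[tr.index_at(149.5)]
        peak_defl = base - tr.y[(tr.t >= 50.0) & (tr.t < 150.0)].min()
        expected = (peak_defl - (base - steady)) / peak_defl
        assert expected > 0.02
        # analysis averages the final 10% of the step for the steady state,
        # the oracle reads the endpoint: allow that difference
        assert pf["sag_ratio"] == pytest.approx(expected, rel=0.1)

    def test_spiking_step_rejected(self):
        tr = triangle_trace([(60.0, 25.0)], duration=300.0)
        with pytest.raises(ValueError, match="spik"):
            passive_features(tr, 50.0, 100.0)


class TestClassifyFSIN:
    def test_typical_fast_spiker_passes(self):
        ok, report = classify_fsin({"tau_m": 15.0, "fi_slope": 0.5,
                                    "r_in": 150.0, "upstroke_downstroke": 1.2})
        assert ok and all(report.values())

    def test_high_input_resistance_fails(self):
        ok, report = classify_fsin({"tau_m": 15.0, "fi_slope": 0.5,
                                    "r_in": 250.0, "upstroke_downstroke": 1.2})
        assert not ok and not report["r_in"] and report["tau_m"]

    @pytest.mark.parametrize("key,value", [
        ("tau_m", 20.0), ("fi_slope", 0.2), ("r_in", 200.0),
        ("upstroke_downstroke", 1.7)])
    def test_boundary_values_fail_strict_inequalities(self, key, value):
        profile = {"tau_m": 15.0, "fi_slope": 0.5, "r_in": 150.0,
                   "upstroke_downstroke": 1.2}
        profile[key] = value
        ok, report = classify_fsin(profile)
        assert not ok and not report[key]

    def test_missing_measure_named(self):
        with pytest.raises(ValueError, match="fi_slope"):
            classify_fsin({"tau_m": 15.0, "r_in": 100.0,
                           "upstroke_downstroke": 1.0})


class TestPnSubtraction:
    @given(cap=st.floats(1.0, 50.0), leak=st.floats(0.1, 5.0),
           seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_annihilates_linear_responses(self, cap, leak, seed):
        """A purely linear (capacitive + leak) cell leaves zero residual."""
        art = ArtifactSpec(cap_amp_per_mv=cap, cap_tau=0.05, leak_g=leak)
        data = gen_na_sweeps(NaTruth(g_max=0.0), artifact=art, seed=seed)
        act = data["activation"]
        corr = pn_subtract(act.sweeps, data["prepulse_sweeps"], act.command_v,
                           act.dt, holding=data["holding"])
        assert np.abs(corr).max() < 1e-8 * max(1.0, np.abs(act.sweeps).max())

    def test_recovers_na_component_under_artifact(self):
        clean = gen_na_sweeps(artifact=ArtifactSpec(0.0, 0.05, 0.0))
        dirty = gen_na_sweeps()
        corr = pn_subtract(dirty["activation"].sweeps, dirty["prepulse_sweeps"],
                           dirty["activation"].command_v,
                           dirty["activation"].dt, holding=dirty["holding"])
        ref = pn_subtract(clean["activation"].sweeps, clean["prepulse_sweeps"],
                          clean["activation"].command_v,
                          clean["activation"].dt, holding=clean["holding"])
        assert np.abs(corr - ref).max() < 1e-6 * np.abs(ref).max()

    def test_unit_scale_is_mean_subtraction(self):
        data = gen_na_sweeps()
        pre = data["prepulse_sweeps"]
        raw = pre[:1]
        corr = pn_subtract(raw, pre, [-40.0], data["activation"].dt,
                           holding=data["holding"], lowpass_khz=1e9)
        assert np.allclose(corr[0], raw[0] - pre.mean(axis=0))

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            pn_subtract(np.zeros((2, 100)), np.zeros((2, 90)), [0, 0], 0.01)


def _analyze(data):
    act, inact = data["activation"], data["inactivation"]
    corr_act = pn_subtract(act.sweeps, data["prepulse_sweeps"], act.command_v,
                           act.dt, holding=data["holding"])
    corr_in = pn_subtract(inact.sweeps, data["prepulse_sweeps"],
                          np.zeros(inact.command_v.size), inact.dt,
                          holding=data["holding"])
    return na_curves_and_fits(
        SweepFamily(corr_act, act.dt, act.command_v, act.pulse_window),
        SweepFamily(corr_in, inact.dt, inact.command_v, inact.pulse_window),
        data["recovery"])


class TestNaCurves:
    def test_noiseless_parameter_recovery(self):
        truth = NaTruth(v_half_act=-51.6, k_act=6.0, v_half_inact=-25.6,
                        k_inact=6.5)
        res = _analyze(gen_na_sweeps(truth))
        assert res.activation.v_half == pytest.approx(-51.6, abs=0.1)
        assert res.inactivation.v_half == pytest.approx(-25.6, abs=0.1)
        assert res.activation.slope_factor == pytest.approx(6.0, rel=0.01)
        assert res.inactivation.slope_factor == pytest.approx(6.5, rel=0.01)
        assert res.activation.accepted and res.inactivation.accepted
        # kinetics within 1%
        for v, tau, r2 in res.tau_activation:
            if r2 > 0.99:
                assert tau == pytest.approx(truth.tau_act(v), rel=0.01)
        for (v_rec, tau, _r2), (v_true, tau_true) in zip(
                res.tau_recovery, truth.tau_recovery):
            assert tau == pytest.approx(tau_true, rel=0.01)

    def test_availability_is_half_at_v_half(self):
        assert boltzmann_inact(-25.6, -25.6, 6.5) == pytest.approx(0.5)
        assert boltzmann_act(-51.6, -51.6, 6.0) == pytest.approx(0.5)

    def test_r2_gate_boundary(self):
        assert not BoltzmannFit(0, 1, 1, r_squared=0.85).accepted
        assert not BoltzmannFit(0, 1, 1, r_squared=0.849).accepted
        assert BoltzmannFit(0, 1, 1, r_squared=0.851).accepted

    def test_noisy_fit_excluded_by_r2_gate(self):
        """Noise heavy enough to destroy the Boltzmann shape trips the gate."""
        rng = np.random.default_rng(0)
        v = np.arange(-100.0, -5.0, 10.0)
        g = boltzmann_inact(v, -25.6, 6.5) + rng.normal(0, 1.5, v.size)
        fit = fit_boltzmann(v, g, "inactivation")
        assert not fit.accepted


class TestConnectionAnalysis:
    def test_noiseless_epsp_recovery(self):
        pre, post, gt = gen_connection_traces(
            "epsp", EventSpec(latency=1.31, amplitude=1.65, failure_rate=0.0),
            TrainSpec(n_pulses=1), dt=0.01)
        met = connection_epsp_analysis(pre, [post] * 5)
        assert met["amplitude"] == pytest.approx(1.65, rel=0.02)
        assert met["onset_latency"] == pytest.approx(1.31, abs=0.05)

    def test_too_few_repeats_rejected(self):
        pre, post, _ = gen_connection_traces("epsp", train=TrainSpec(n_pulses=1))
        with pytest.raises(ValueError, match=">= 5"):
            connection_epsp_analysis(pre, [post] * 3)

    def test_average_of_identical_traces_matches_single(self):
        pre, post, _ = gen_connection_traces(
            "epsp", EventSpec(latency=1.0, amplitude=1.2, failure_rate=0.0),
            TrainSpec(n_pulses=1), dt=0.01)
        m10 = connection_epsp_analysis(pre, [post] * 10)
        m5 = connection_epsp_analysis(pre, [post] * 5)
        for key in m5:
            assert m10[key] == pytest.approx(m5[key], rel=1e-9)


class TestPSCEvents:
    def test_fixed_latency_median(self):
        pre, post, _ = gen_connection_traces(
            "psc", EventSpec(latency=0.84, amplitude=155.0, failure_rate=0.0),
            dt=0.02)
        summary = summarize_events(psc_event_analysis(pre, post))
        assert summary["median_latency"] == pytest.approx(0.84, abs=0.05)
        assert summary["median_amplitude"] == pytest.approx(-155.0, rel=0.02)
        assert summary["n_failures"] == 0

    def test_slow_event_flagged_polysynaptic(self):
        pre, post, _ = gen_connection_traces(
            "psc", EventSpec(latency=3.0, amplitude=100.0, failure_rate=0.0),
            dt=0.02)
        events = psc_event_analysis(pre, post)
        assert all(not e.failure for e in events)
        assert all(not e.monosynaptic for e in events)

    def test_failure_bookkeeping_matches_generator(self):
        pre, post, gt = gen_connection_traces(
            "psc", EventSpec(latency=0.9, amplitude=120.0, failure_rate=0.3),
            TrainSpec(n_pulses=40, rate_hz=20.0), dt=0.02, seed=7)
        events = psc_event_analysis(pre, post)
        true_failures = sum(r["failure"] for r in gt.params["events"])
        assert sum(e.failure for e in events) == true_failures

    def test_no_presynaptic_aps_is_error(self):
        flat = Trace(np.full(5000, -65.0), 0.02, units="mV")
        post = Trace(np.zeros(5000), 0.02, units="pA")
        with pytest.raises(ValueError, match="presynaptic"):
            psc_event_analysis(flat, post)
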