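"""Analyze synthetic recordings with known ground truth.

Generates (i) a noisy fast-spiking AP trace, (ii) voltage-clamp Na+ sweep
families with capacitive/leak artifacts, and (iii) a paired FSIN→pyramidal
recording, then runs the corresponding analyses and prints estimates next to
the generating truth.
"""

import numpy as np

from fsin.ephys import (SweepFamily, ap_waveform_features, detect_aps,
                        na_curves_and_fits, pn_subtract, psc_event_analysis,
                        summarize_events)
from fsin.synth import (APSpec, EventSpec, NaTruth, gen_ap_trace,
                        gen_connection_traces, gen_na_sweeps)

# --- AP waveform -----------------------------------------------------------
spec = APSpec(threshold=-42.2, onset_rapidity=41.9, rise_speed=412.0,
              fall_speed=-191.0, peak=30.0, half_width=0.5)
trace, _ = gen_ap_trace(spec, times=[20.0], noise_sd=0.05, seed=1)
f = ap_waveform_features(trace, detect_aps(trace)[0])
print("AP waveform (estimate | truth):")
print(f"  threshold      {f.threshold:8.2f} | {spec.threshold} mV")
print(f"  onset rapidity {f.onset_rapidity:8.2f} | {spec.onset_rapidity} /ms")
print(f"  rise speed     {f.rise_speed:8.1f} | {spec.rise_speed} mV/ms")
print(f"  half-width     {f.half_width:8.3f} | {spec.half_width} ms")

# --- Na+ currents ----------------------------------------------------------
truth = NaTruth()
data = gen_na_sweeps(truth, noise_sd=1.0, seed=2)
act, inact = data["activation"], data["inactivation"]
corr_act = pn_subtract(act.sweeps, data["prepulse_sweeps"], act.command_v,
                       act.dt, holding=data["holding"])
corr_in = pn_subtract(inact.sweeps, data["prepulse_sweeps"],
                      np.zeros(inact.command_v.size), inact.dt,
                      holding=data["holding"])
res = na_curves_and_fits(
    SweepFamily(corr_act, act.dt, act.command_v, act.pulse_window),
    SweepFamily(corr_in, inact.dt, inact.command_v, inact.pulse_window),
    data["recovery"])
print("\nNa+ currents after P/n artifact subtraction (estimate | truth):")
print(f"  V1/2 activation   {res.activation.v_half:8.2f} | {truth.v_half_act} mV"
      f"   (R² = {res.activation.r_squared:.3f}, accepted: {res.activation.accepted})")
print(f"  V1/2 inactivation {res.inactivation.v_half:8.2f} | {truth.v_half_inact} mV")
print(f"  recovery τ at -80 {res.tau_recovery[0][1]:8.2f} | "
      f"{truth.tau_recovery[0][1]} ms")

# --- unitary PSCs ----------------------------------------------------------
pre, post, gt = gen_connection_traces(
    "psc", EventSpec(latency=("normal", 0.84, 0.1), amplitude=155.0,
                     failure_rate=0.05), noise_sd=2.0, seed=3)
summary = summarize_events(psc_event_analysis(pre, post))
print("\nunitary PSC events (8-AP train, 5% failure rate):")
print(f"  events analyzed    {summary['n_events']}, failures "
      f"{summary['n_failures']}, monosynaptic {summary['n_monosynaptic']}")
print(f"  median latency     {summary['median_latency']:.2f} ms (truth ~0.84)")
print(f"  median amplitude   {summary['median_amplitude']:.0f} pA (truth -155)")
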