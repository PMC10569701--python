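# fsin — fast-spiking interneuron modeling and electrophysiology analysis

Cortical fast-spiking interneurons (FSINs) inhibit neighboring pyramidal
neurons within a few milliseconds, fast enough to pace gamma-band network
activity. Human FSINs face a geometric problem: their dendritic paths are
two- to three-fold longer than in mouse, which passive cable theory says
should attenuate and slow incoming synaptic input. `fsin` is a toolkit for
studying how FSIN structure and biophysics preserve this fast input–output
loop. It provides:

* **Parametric morphologies** — artificial FSIN arbors built from five
  interpretable parameters (primary dendrite count, nonterminal/terminal
  segment lengths, base/tip diameters), SWC I/O with cut-terminal
  annotations, morphometrics with closed-form oracles, and dendritic scaling.
* **A branched-cable Hodgkin–Huxley model** — Na⁺/K⁺/HCN/leak conductances
  per region (dendrite, soma, axon), alpha synapses, implicit
  (Crank–Nicolson/backward-Euler) integration with a Hines direct solve,
  numba-compiled; 2 µs resolution for AP-timing questions.
* **Feature-objective model fitting** — 20 electrophysiological objectives
  under four protocols; SD-scaled fitness; a reproducible real-coded
  evolutionary optimizer (SBX + polynomial mutation) over the 13 free
  conductance parameters; the packaged default parameter set is such a fit on
  the species-averaged morphology.
* **In-silico experiments** — EPSP attenuation vs synapse distance, random
  multi-synapse configurations, synaptic/conductance "boost" mechanisms,
  AP-delay scans, dendritic-scaling effects on AP initiation, and
  disynaptic-delay composition.
* **Trace analysis** — AP detection and phase-plane features (threshold at 5%
  of maximal rise slope, onset rapidity, rise/fall speeds, half-width),
  passive features, four-criterion fast-spiking classification, Na⁺-current
  P/n artifact subtraction with Boltzmann/exponential fits and an R² > 0.85
  gate, and unitary EPSP/PSC event analysis with failure exclusion and the
  < 2.5 ms monosynaptic window.
* **Synthetic data** — generators with exact ground truth for every analysis
  (AP traces, Na⁺ sweep families with linear artifacts, paired-recording
  traces, jittered/cut morphologies), so the whole pipeline is testable
  without any experimental download.

The model at the core: membrane voltage on a compartmentalized tree obeys

    C_m dV_i/dt = − Σ_ion ḡ_ion m^p h^q (V_i − E_ion) + Σ_j g_ij (V_j − V_i)
                  + I_inj(t) + g_syn(t) (E_syn − V_i)

with transient Na⁺ (m³h), delayed-rectifier K⁺ (n⁴), single-gate HCN, and
leak; the 13 free parameters (4 densities × 3 regions + an axonal Na⁺
voltage shift) are fitted to feature objectives such as time-to-first-spike
10 ± 1 ms at +200 pA, AP half-width 0.3 ± 0.05 ms, and an AIS-vs-soma
first-spike lead of 0.05 ± 0.005 ms. See `docs/methods.md` for the full
model description and numerical choices.

## Worked example

```python
from fsin import build_cell, generate_morphology, simulate, StepStim
from fsin.ephys import ap_waveform_features, detect_aps
from fsin.presets import AVERAGED_MORPHO, FITTED_DENSITIES

cell = build_cell(generate_morphology(AVERAGED_MORPHO), FITTED_DENSITIES)
trace = simulate(cell, stims=[StepStim(200.0, 10.0, 100.0)],
                 record_sites=("soma",), dt=0.005, t_stop=112.0)["soma"]
peaks = detect_aps(trace)
f = ap_waveform_features(trace, peaks[0], target_dt=trace.dt)
print(f"{peaks.size} spikes; first at {peaks[0]-10.0:.2f} ms after onset; "
      f"half-width {f.half_width:.3f} ms; rise speed {f.rise_speed:.0f} mV/ms")
```

prints

```
11 spikes; first at 10.95 ms after onset; half-width 0.311 ms; rise speed 370 mV/ms
```

— a fast-spiking train whose first-spike latency, spike width and rise speed
sit on the fitted objectives (10 ± 1 ms, 0.3 ± 0.05 ms, 350 ± 70 mV/ms). The scripts in
`examples/` walk through each capability the same way: morphology metrics,
model firing features, a miniature evolutionary fit, dendritic filtering and
the doubled-synapse rescue, dendritic scaling and the disynaptic delay
budget, and ground-truth trace analysis.

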