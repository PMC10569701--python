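# Methods

`fsin` models cortical fast-spiking interneurons (FSINs) — the
parvalbumin-type basket cells that supply fast perisomatic inhibition — as
conductance-based compartmental cables on parametric morphologies, and
implements the trace analyses used on experimental FSIN recordings. This note
documents the models, the numerical choices, and what the synthetic-data
generators do and do not emulate.

## Parametric morphologies

Artificial dendritic arbors are built from five interpretable parameters:
number of primary dendrites, nonterminal segment length (NT), terminal segment
length (T), and the dendritic diameter at the base and at the tips. Every
dendrite is an identical binary tree whose terminal segments sit at a fixed
branch order (default 3, the typical terminal order of FSIN dendrites in both
species); diameter tapers linearly with path distance from the soma, each SWC
node's radius sampled at its edge midpoint. A single unbranched axon
(default 500 µm × 0.2 µm) attaches to the soma. The 3-D embedding is a purely
cosmetic radial fan in a plane; all path metrics are embedding-independent.

Species presets carry the measured dendritic statistics: human — 5 primary
dendrites, NT 17.2 µm, T 216 µm; mouse — 7, 25.7 µm, 72 µm. Base/terminal
diameters (human 1.5/0.4 µm, mouse 1.0/0.3 µm) are calibration constants
chosen so the human arbor is thicker at every branch order, since the diameter
data are reported only graphically. The soma is a cylinder with length equal
to its diameter (default 15 µm), which gives it the surface area of the
equivalent sphere; soma size is likewise a calibration constant.

Because the trees are parametric, every morphometric has a closed form
(per-dendrite length `Σ_{k<order} 2^(k−1)·NT + 2^(order−1)·T`, branch points
`2^(order−1) − 1`), and the morphometric extractor recovers the generator's
parameters exactly — the property tests rely on this inverse.

Cut terminals (dendrites truncated by slicing) are carried as explicit
annotations in a plain-text sidecar next to the SWC file, never inferred from
geometry: identifying them is a judgment made when reconstructing a real cell,
not a computable property of the tree. Terminal-path and terminal-length
statistics can exclude them.

## The cable model

The membrane carries four conductances per region (dendrite, soma, axon):
transient Na⁺ (m³h), delayed-rectifier K⁺ (n⁴), a single-gate slow HCN
current, and ohmic leak. Fixed constants: C_m 0.9 µF/cm², R_a 100 Ω·cm,
E_leak −75 mV, E_Na +64 mV, E_K −85 mV, E_HCN −45 mV. Synapses are alpha
conductances g(t) = g_max·((t−t₀)/τ)·exp(1−(t−t₀)/τ) with τ = 0.4 ms and
reversal 0 mV.

The 13 free parameters are the four conductance densities in each region plus
a voltage shift applied to the axonal Na⁺ gating (mimicking low-threshold
Nav1.6 channels concentrated in the axon).

**Gating kinetics.** No gating-rate functions accompany the reference
densities, so a kinetics set had to be chosen. We adopt the Wang–Buzsáki fast-spiking
formulation (transient Na⁺ with m³h, delayed-rectifier K⁺ n⁴) with the
temperature-like speedup factor 5 applied to h and n — and also to m: the
original treats activation as instantaneous, and keeping m as an ODE at its
raw rates (τ_m ≈ 0.2–0.5 ms) makes spiking impossible; the sped-up gate
(τ_m ≈ 0.05–0.1 ms) preserves regenerative initiation while remaining a state
variable, which the onset-rapidity analyses need. HCN uses
q∞ = 1/(1+exp((V+82)/7)) with a constant 40 ms time constant. The set is
calibrated against the 34 °C feature objectives; no explicit Q10 model is
applied. Consequence: the reference densities are *not* expected to reproduce their
original behavior under these kinetics (densities are meaningful only with
the mechanisms they were fitted under); they ship as
`presets.REFERENCE_DENSITIES` for comparison
and as the scale that defines default search bounds, while the packaged
default `presets.FITTED_DENSITIES` is this package's own evolutionary re-fit
(below).

**Discretization and integration.** The tree is split into cylindrical
compartments of at most 25 µm (per unbranched section, `ceil(L/25)` equal
pieces, diameter interpolated at the compartment midpoint). Voltage advances
by a theta-method on the branched cable — θ = 0.5 (Crank–Nicolson) by
default, θ = 1 (backward Euler) for settling — with the tree-structured
linear system solved directly in Hines order each step. Gating variables use
exact exponential (Rush–Larsen) updates from voltage-indexed lookup tables
(0.05 mV grid, linear interpolation), staggered by half a step relative to
voltage so Crank–Nicolson keeps second-order accuracy. The kernel is
numba-compiled.

Time steps: 25 µs for subthreshold/long protocols, 5 µs for the spiking step
protocol, 2 µs for AP-timing protocols (the AIS-vs-soma lead objective is
0.05 ± 0.005 ms, and experimental onset-rapidity windows span 6–12 µs; spike
times are refined by parabolic interpolation of the peak). Halving the 2 µs
step moves an AP peak by well under 1 µs (tested). Each simulation starts
from E_leak with steady-state gates and runs a 200 ms stimulus-free settle
(backward Euler, 100 µs) before the recorded phase, which removes
initialization transients; HCN makes the true resting potential slightly
depolarized relative to E_leak.

Units are mV, ms, µm, pA, nS, pS/µm², µF/cm², Ω·cm throughout; the
conversions (1 pS/µm² ≡ 10⁻⁴ S/cm², 1 µF/cm² ≡ 0.01 pF/µm²,
1 Ω·cm ≡ 10⁴ Ω·µm) are centralized in `fsin.cable` and exercised by the
closed-form physics tests (RC charging, sealed-end cable input resistance,
exact charge conservation, passive reciprocity).

**Landmarks.** "AIS" is the axonal span 0–40 µm from the soma (recorded at
its midpoint) and "distal axon" the compartment nearest 300 µm; both are
configurable — they are named landmarks without canonical coordinates.

## Model fitting

Twenty feature objectives over four protocols (100 ms ±current steps, an
800 pA/4 ms pulse, and a distal synapse volley) define the fitness: each
contributes |feature − target| / SD, an undefined feature (e.g. spike timing
of a model that does not spike) costs a fixed 250, and the total is the sum.
Feature names that lack a canonical formula are fixed here as:
time to first spike = stimulus onset to first AP *peak*; AP half-width at half
height between threshold and peak; absolute AHP = minimum voltage between the
last spike and stimulus end; sag ratio = (peak − steady deflection)/peak
deflection on the −100 pA step; AIS−soma lead = t_peak(soma) − t_peak(AIS),
positive when the AP initiates in the AIS first.

The synapse-activation protocol uses four synapses of 0.01 µS (10 nS) each,
placed at 108 µm on four distinct primary dendrites — strong enough to make
its single-spike objectives attainable.

The optimizer is a bounded real-coded evolutionary algorithm: binary
tournament parent selection, simulated-binary crossover and polynomial
mutation (both with distribution index η = 10, probabilities 0.7/0.7), and
elitist (µ+λ) survivor selection; single-objective total score, matching the
acceptance rule "highest fitness = lowest total deviation". Runs are exactly
reproducible from the seed, and the per-generation best is non-increasing by
construction. During optimization the AP protocols run at a 10 µs step for
speed; the final model is always re-evaluated at full resolution.

Search bounds default to [0, 10×] each reference density (shift in
[−6.2, 0] mV). For the *packaged* fit the dendritic Na⁺ and K⁺ densities are
instead capped at 2× their reference values: without that cap the optimizer
can satisfy every objective with dendritically generated APs (a degenerate
optimum with ~7× the reference dendritic Na⁺ density and nearly passive
soma), which inverts the dendritic-size dependence of AP initiation. FSIN
dendrites are only weakly excitable and the reference model itself used
moderate dendritic densities, so the cap encodes that the model should
initiate APs axosomatically. The fit runs on the *averaged-species*
morphology (6 primary dendrites, NT 21.45 µm, T 144 µm — the mean of the two
species parameter sets) so neither species biases the densities; species
models then swap in their morphology without re-fitting.

## In-silico experiments

All experiments are pure functions of (cell specification, protocol, seed).

* **EPSP distance scan** — one subthreshold alpha synapse per run at graded
  path distances; somatic amplitude falls and rise time grows monotonically
  with distance (passive filtering), and the human model yields smaller
  somatic EPSPs than the mouse model at matched distance.
* **Random synapse configurations** — n synapses at locations drawn uniformly
  over total dendritic cable length (not per branch), seed-reproducible.
* **Boost mechanisms** — `synapse_x2` doubles synaptic conductance;
  `ih_gradient`/`leak_gradient` multiply the dendritic HCN/leak density by
  1 + s·x/x_max (x = path distance; slope s default 2); `stretched_conductance`
  rescales all dendritic densities by x/x̄ (area-weighted), i.e. redistributes
  conductance distally at exactly constant total. The linear forms are this
  package's concrete choice; the gradient mechanisms appear in the literature
  without a single canonical functional form.
* **AP-delay scan** — for each of 20 graded (or random) path distances, a
  cohort of synapses (default 20 × 3 nS) is activated simultaneously,
  distributed over the distinct branches crossing that distance; delay =
  somatic AP peak − synapse onset; non-spiking distances are recorded and
  excluded with a count. The drive must be distributed because a single
  alpha-conductance site saturates at the synaptic reversal potential and can
  never fire the cell from distal dendrite, however large its conductance.
  One cohort conductance is used across conditions for comparability
  (`find_suprathreshold_gsyn` grid-searches it when needed).
* **Dendritic scaling** — dendritic lengths ×0.5/1.0/1.5 under an identical
  somatic pulse; larger dendritic load lowers AP threshold, steepens onset
  rapidity and increases the AIS lead (greater current sink decouples the
  initiation site).
* **Disynaptic-delay composition** — the total
  pyramidal → FSIN → pyramidal inhibition delay as the plain sum of its four
  stage delays (EPSP onset latency, dendritic transfer, AIS lead, inhibitory
  output latency).

## Trace analysis

AP detection: peaks ≥ −10 mV, prominence ≥ 20 mV, separation ≥ 2 ms (within a
closer cluster the higher peak wins). Waveform features: threshold is the
voltage where dV/dt first reaches 5% of the maximal rise slope, located by
walking *backward* from the maximal-slope point (a forward scan lets baseline
derivative noise trip the rule); onset rapidity is the slope of a linear fit
of dV/dt vs V from 6 µs before to 12 µs after the 40 mV/ms phase-plane
crossing (traces coarser than 2 µs are spline-resampled, logged); rise/fall
speeds are slopes of linear fits over the 30–70% threshold-to-peak span.
Before differentiation the waveform is smoothed with a cubic Savitzky–Golay
filter over 20 µs — short against AP curvature, so noiseless features are
exact while derivative noise is suppressed — and the peak voltage comes from
a local quadratic fit (or flat-run mean) of the *raw* samples, not a max
statistic. Estimator properties under noise, measured by Monte-Carlo against
the generators: threshold, rapidity and rise/fall speeds are statistically
centered on truth; peak and half-width carry an irreducible resolution floor
(extremum localization, sample-grid quantization) that the tests bound
explicitly rather than pretend away.

Passive features from the −100 pA step: deflection (baseline − steady state),
sag ratio as above, post-stimulus decay τ and charging τ_m by log-linear
exponential fits over the 90→20% relaxation span, R_in = deflection/|I|.
Fast-spiking classification requires, strictly: τ_m < 20 ms, F/I slope >
0.2 Hz/pA, R_in < 200 MΩ, upstroke/downstroke ratio < 1.7; boundary values
fail.

Na⁺ currents: P/n subtraction averages the −40 mV prepulse responses, scales
the template by each pulse's step amplitude and subtracts (exact for any
linear capacitive+leak system — a property test drives random linear cells to
zero residual), then low-pass filters at 20 kHz (zero-phase 4th-order
Butterworth; the filter family is this package's documented choice). Peak
amplitudes are taken relative to the end-of-pulse steady state. Activation
conductance G = I_peak/(V − E_Na); activation/availability curves are fitted
with Boltzmann functions G_max/(1+exp(±(V_half−V)/k)); fits carry R² and the
acceptance gate is strictly R² > 0.85. Activation and inactivation time
constants come from a joint fit of I(t) = −A(1−e^{−t/τa})e^{−t/τi} to each
pulse (the rising and decaying exponentials estimated together), recovery τ
from 1−e^{−Δt/τ} fits to paired-pulse amplitude ratios per recovery voltage.
A liquid-junction-potential offset (default 0, configurable) is added to
command voltages at analysis time.

Synaptic events: unitary EPSP features are read from the average of ≥5
repetitions, referenced to the presynaptic AP peak. EPSP/PSC onset = first
time the signal exceeds baseline mean + 3×baseline SD *and* subsequently
reaches ≥20% of the event peak (there is no canonical onset rule; this one
is config-overridable). Per-AP PSC events carry onset latency,
amplitude and 10–90% rise time; APs without a detectable event are failures,
excluded from latency statistics; events with latency < 2.5 ms form the
monosynaptic subset; summaries report per-connection medians and the KDE mode
of the latency distribution.

## Synthetic data

Each generator is the exact adjoint of its analysis: piecewise-analytic AP
waveforms (ramp → exponential takeoff whose phase-plane slope *is* the onset
rapidity and on which the 5% rule lands exactly at the requested threshold →
linear rise → flat cap sized to the requested half-width → linear fall), Na⁺
sweep families from Boltzmann × exponential kinetics plus a linear
capacitive/leak artifact and −40 mV prepulse sweeps, paired-recording traces
with events drawn per AP from configurable latency/amplitude distributions
and failure rates, and jittered/cut-terminal morphologies. Trace noise is
Gaussian, band-limited (default 10 kHz) before scaling to the requested SD —
per-sample white noise at 500 kHz sampling would be nonphysical for
amplifier recordings. Generator defaults follow the reported experimental
statistics (unitary EPSP 1.65/1.22 mV, PSC latency modes 0.74/1.06 ms,
5% failure rate, brief FS AP shapes) as *realistic fixtures*, not as
reproduction targets.

What the generators do not emulate: electrode/access-resistance artifacts
beyond the linear term, temperature drift, trial-to-trial kinetic
variability, dendritic nonlinearities in the synthetic EPSP/PSC shapes, and
real reconstruction noise (z-shrinkage, diameter quantization) in
morphologies. Passing recovery tests therefore show the analyses are correct
and well-conditioned, not that they are robust to every artifact of real
recordings.

## Problem sizes

The default test and acceptance runs use the sizes chosen for a single-CPU
desk run: the averaged-species model has ≈180 compartments; scans use 5–6
distances and 4–6 random configurations; the reduced evolutionary budget is
25 generations × 16 offspring warm-started from the packaged fit (the
packaged fit itself used ≈115 generations × 100 offspring in two seeded
stages); Monte-Carlo recovery studies use 100 seeds.

## Known limitations

* Kinetics are calibrated, not measured: absolute AP shape agreement with any
  particular recorded cell is limited by the chosen rate functions, which is
  precisely why densities are re-fitted rather than copied.
* Myelination, calcium dynamics, stochastic channels and network context are
  out of scope; the axon is a uniform passive-diameter cable with one Na⁺
  voltage-shift degree of freedom.
* Under these kinetics the brief-pulse first-spike-latency objective trades
  off against AP amplitude through the somatic Na⁺ density (parameter scans
  show the 2.9 ms latency is reachable only where the somatic AP collapses);
  the packaged fit is the lowest-total-deviation compromise and sits ~0.4 ms
  early on that single objective while meeting the other timing objectives
  within their SDs.
* The onset-rapidity estimator needs low-noise, high-bandwidth traces; at
  0.5 mV broadband noise its 18 µs fit window is noise-dominated and the
  estimate should not be trusted (the tests quantify this).
* `scale_dendrites` scales segment lengths about the soma and leaves
  diameters untouched, matching the scaling experiment's design; it is not a
  general morphological "growth" model.
* With a uniform 0.2 µm axon the soma-AIS axial conductance is ~1 nS, so the
  somatic upstroke is locally regenerated rather than axon-driven. Dendritic
  up-scaling then steepens onset rapidity and lengthens the AIS lead (both
  reproduced), but the somatic 5%-of-max-slope threshold rises slightly with
  load instead of falling: at upstroke frequencies the dendritic AC length
  constant (~70 µm) hides length changes from the maximal slope while the
  slow pre-spike foot does feel the load. A lower threshold under load would
  require an initiation site that stays tightly coupled to the dendritic
  sink during the upstroke (e.g. a thick, tapering AIS), which this model
  family deliberately does not include.
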