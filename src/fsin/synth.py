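"""Synthetic-data generators with known ground truth.

Every analysis operation in :mod:`fsin.ephys` has a paired generator here whose
noiseless output it inverts exactly: AP traces built from piecewise-analytic
waveforms whose threshold/rapidity/speeds/half-width equal the requested spec;
voltage-clamp Na+ sweep families following Boltzmann voltage dependence and
exponential kinetics with linear capacitive/leak artifacts for P/n testing;
paired-recording traces with unitary synaptic events drawn from configurable
latency/amplitude distributions and failure rates; and jittered morphologies
with labeled cut terminals.

Default fixture parameters follow the experimentally reported means/medians
for human and mouse fast-spiking interneurons (e.g. unitary EPSP amplitudes of
1.65 / 1.22 mV, monosynaptic PSC latency modes of 0.74 / 1.06 ms); they are
realistic fixture defaults, not reproduction targets.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .ephys import boltzmann_act, boltzmann_inact, RecoveryFamily, SweepFamily
from .morphology import DEND, MorphoParams, NeuronTree, generate_morphology
from .traceio import Trace


@dataclass
class GroundTruth:
    """True parameter values behind a generated dataset."""

    generator: str
    params: dict
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"generator": self.generator, "seed": self.seed,
                       "params": self.params}, fh, indent=1, default=str)


# ---------------------------------------------------------------------------
# Action-potential traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class APSpec:
    """Analytic AP waveform specification.

    The waveform is a slow depolarizing ramp, an exponential takeoff
    dV/dt = onset_rapidity * (V - V0) -- whose phase-plane slope is the onset
    rapidity and on which the 5%-of-max-slope threshold rule lands exactly at
    ``threshold`` -- a linear rise at ``rise_speed``, a flat cap at ``peak``
    sized so the half-width comes out exactly, and a linear fall at
    ``fall_speed`` back to baseline.
    """

    threshold: float = -42.2       # mV
    onset_rapidity: float = 41.9   # 1/ms
    rise_speed: float = 412.0      # mV/ms
    fall_speed: float = -191.0     # mV/ms
    peak: float = 30.0             # mV
    half_width: float = 0.5        # ms
    baseline: float = -65.0        # mV

    def __post_init__(self):
        if self.rise_speed <= 0 or self.fall_speed >= 0:
            raise ValueError("rise_speed must be > 0 and fall_speed < 0")
        if not self.baseline < self.threshold < self.peak:
            raise ValueError("need baseline < threshold < peak")
        half = self.threshold + 0.5 * (self.peak - self.threshold)
        min_hw = ((self.peak - half) / self.rise_speed
                  + (self.peak - half) / abs(self.fall_speed))
        if self.half_width < min_hw:
            raise ValueError(
                f"half_width {self.half_width} ms infeasible: rise/fall speeds "
                f"imply at least {min_hw:.4f} ms")


def _ap_segments(spec: APSpec, ramp_slope_frac: float = 0.02):
    """Piecewise description [(duration, eval_fn(t_local)), ...] ending at peak cap."""
    a, S, F = spec.onset_rapidity, spec.rise_speed, abs(spec.fall_speed)
    v0 = spec.threshold - 0.05 * S / a       # takeoff asymptote
    ramp_slope = ramp_slope_frac * S
    eps = ramp_slope / a                     # exp phase start offset above v0
    v_e0 = v0 + eps
    if v_e0 <= spec.baseline:
        raise ValueError("baseline too close to threshold for the takeoff phase")
    t_ramp = (v_e0 - spec.baseline) / ramp_slope
    v1 = v0 + S / a                          # exp phase ends when slope = S
    t_exp = np.log((v1 - v0) / eps) / a
    t_lin = (spec.peak - v1) / S
    half = spec.threshold + 0.5 * (spec.peak - spec.threshold)
    cap = spec.half_width - (spec.peak - half) / S - (spec.peak - half) / F
    t_fall = (spec.peak - spec.baseline) / F
    segs = [
        (t_ramp, lambda t: spec.baseline + ramp_slope * t),
        (t_exp, lambda t: v0 + eps * np.exp(a * t)),
        (t_lin, lambda t: v1 + S * t),
        (cap, lambda t: np.full_like(t, spec.peak)),
        (t_fall, lambda t: spec.peak - F * t),
    ]
    t_peak_mid = t_ramp + t_exp + t_lin + cap / 2.0
    return segs, t_peak_mid


def gen_ap_trace(spec: APSpec = APSpec(), times=(50.0,), dt: float = 0.002,
                 duration: float | None = None, noise_sd: float = 0.0,
                 seed: int = 0, noise_bandwidth_khz: float = 10.0):
    """Current-clamp voltage trace with analytic APs at ``times`` (peak times).

    In the noiseless limit :func:`fsin.ephys.ap_waveform_features` recovers the
    spec's threshold, onset rapidity, rise/fall speeds, peak and half-width
    exactly (up to sampling resolution).  Noise is band-limited to
    ``noise_bandwidth_khz`` (amplifier recordings are anti-alias filtered, so
    per-sample white noise at 500 kHz would be nonphysical) and scaled to the
    requested SD.
    """
    segs, t_peak_mid = _ap_segments(spec)
    total = sum(d for d, _ in segs)
    times = np.sort(np.asarray(times, float))
    if duration is None:
        duration = float(times[-1]) + total + 20.0
    t = np.arange(0.0, duration, dt)
    y = np.full(t.size, spec.baseline)
    for ap_t in times:
        start = ap_t - t_peak_mid
        off = start
        for seg_dur, fn in segs:
            sel = (t >= off) & (t < off + seg_dur)
            if sel.any():
                y[sel] = fn(t[sel] - off)
            off += seg_dur
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        from scipy.ndimage import gaussian_filter1d

        white = rng.normal(0.0, 1.0, y.size)
        sigma_samples = 1.0 / (2.0 * np.pi * noise_bandwidth_khz * dt)
        colored = gaussian_filter1d(white, max(sigma_samples, 1e-6))
        colored *= noise_sd / max(colored.std(), 1e-12)
        y = y + colored
    gt = GroundTruth("gen_ap_trace",
                     {**asdict(spec), "times": list(map(float, times)),
                      "noise_sd": noise_sd}, seed)
    return Trace(y, dt, site="soma", units="mV"), gt


# ---------------------------------------------------------------------------
# Na+ current sweep families
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NaTruth:
    """True Na+ current voltage dependence and kinetics."""

    v_half_act: float = -51.6
    k_act: float = 6.0
    v_half_inact: float = -25.6
    k_inact: float = 6.5
    g_max: float = 50.0            # nS
    e_na: float = 64.0
    tau_act_base: float = 0.12     # ms, plus voltage-dependent part
    tau_act_amp: float = 0.35
    tau_inact_base: float = 0.5
    tau_inact_amp: float = 1.5
    tau_recovery: tuple = ((-80.0, 4.0), (-75.0, 5.0), (-70.0, 6.5), (-65.0, 8.5))

    def tau_act(self, v):
        return self.tau_act_base + self.tau_act_amp / (1.0 + np.exp((v + 30.0) / 10.0))

    def tau_inact(self, v):
        return self.tau_inact_base + self.tau_inact_amp / (1.0 + np.exp((v + 40.0) / 12.0))


@dataclass(frozen=True)
class ArtifactSpec:
    """Linear capacitive + leak contamination of voltage-clamp sweeps."""

    cap_amp_per_mv: float = 20.0   # pA of capacitive transient per mV of step
    cap_tau: float = 0.05          # ms
    leak_g: float = 1.0            # nS

    def current(self, t, t_on, t_off, dv):
        """Artifact current for a step of dv mV over [t_on, t_off)."""
        i = np.zeros_like(t)
        on = t >= t_on
        i[on] += self.cap_amp_per_mv * dv * np.exp(-(t[on] - t_on) / self.cap_tau)
        off = t >= t_off
        i[off] -= self.cap_amp_per_mv * dv * np.exp(-(t[off] - t_off) / self.cap_tau)
        i[(t >= t_on) & (t < t_off)] += self.leak_g * dv
        return i


def _na_pulse_current(t_local, v, avail, truth: NaTruth):
    """Inward Na+ current during a pulse to v with availability ``avail``."""
    act = boltzmann_act(v, truth.v_half_act, truth.k_act)
    drive = v - truth.e_na
    ta, ti = truth.tau_act(v), truth.tau_inact(v)
    f = (1.0 - np.exp(-t_local / ta)) * np.exp(-t_local / ti)
    peak_f = f.max() if f.size else 1.0
    amp = truth.g_max * act * avail * drive   # nS * mV = pA (inward: negative)
    return amp * f / peak_f if peak_f > 0 else amp * f


def gen_na_sweeps(truth: NaTruth = NaTruth(), artifact: ArtifactSpec = ArtifactSpec(),
                  noise_sd: float = 0.0, seed: int = 0,
                  holding: float = -90.0, dt: float = 0.01,
                  act_voltages=None, inact_prepulses=None,
                  pulse_ms: float = 30.0, pre_ms: float = 2.0,
                  recovery_delays=None, n_prepulse: int = 5):
    """Voltage-clamp Na+ sweep families under activation / inactivation /
    recovery protocols, with linear artifacts and optional noise.

    Returns a dict with ``activation`` and ``inactivation``
    :class:`~fsin.ephys.SweepFamily` (raw, artifact-contaminated),
    ``prepulse_sweeps`` (five -40 mV steps for P/n subtraction), a list of
    :class:`~fsin.ephys.RecoveryFamily`, and the matching
    :class:`GroundTruth`.
    """
    rng = np.random.default_rng(seed)
    if act_voltages is None:
        act_voltages = np.arange(-70.0, 21.0, 10.0)
    if inact_prepulses is None:
        inact_prepulses = np.arange(-100.0, -4.0, 10.0)
    if recovery_delays is None:
        recovery_delays = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0])
    n_t = int(round((pre_ms + pulse_ms) / dt))
    t = np.arange(n_t) * dt
    i_on = int(round(pre_ms / dt))
    window = (i_on, n_t)

    def sweep(v_pulse, avail, with_na=True):
        y = artifact.current(t, pre_ms, pre_ms + pulse_ms, v_pulse - holding)
        if with_na:
            tl = t[i_on:] - t[i_on]
            y[i_on:] += _na_pulse_current(tl, v_pulse, avail, truth)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, y.size)
        return y

    act_sweeps = np.array([sweep(v, 1.0) for v in act_voltages])
    inact_sweeps = np.array(
        [sweep(0.0, boltzmann_inact(vp, truth.v_half_inact, truth.k_inact))
         for vp in inact_prepulses])
    prepulse = np.array([sweep(-40.0, 0.0, with_na=False)
                         for _ in range(n_prepulse)])

    recovery = []
    for v_rec, tau in truth.tau_recovery:
        ratios = 1.0 - np.exp(-np.asarray(recovery_delays, float) / tau)
        if noise_sd > 0:
            ratios = ratios + rng.normal(0.0, noise_sd * 1e-3, ratios.size)
        recovery.append(RecoveryFamily(v_rec, np.asarray(recovery_delays, float),
                                       ratios))

    gt = GroundTruth("gen_na_sweeps",
                     {**asdict(truth), "artifact": asdict(artifact),
                      "noise_sd": noise_sd, "holding": holding}, seed)
    return {
        "activation": SweepFamily(act_sweeps, dt, np.asarray(act_voltages, float), window),
        "inactivation": SweepFamily(inact_sweeps, dt, np.asarray(inact_prepulses, float), window),
        "prepulse_sweeps": prepulse,
        "recovery": recovery,
        "holding": holding,
        "ground_truth": gt,
    }


# ---------------------------------------------------------------------------
# Paired-recording connection traces
# ---------------------------------------------------------------------------

def _dual_exp(t_local, tau_rise, tau_decay):
    """Difference-of-exponentials normalized to unit peak."""
    if tau_decay <= tau_rise:
        tau_decay = tau_rise * 1.5
    y = np.exp(-t_local / tau_decay) - np.exp(-t_local / tau_rise)
    t_pk = (np.log(tau_decay / tau_rise)
            * tau_rise * tau_decay / (tau_decay - tau_rise))
    pk = np.exp(-t_pk / tau_decay) - np.exp(-t_pk / tau_rise)
    return y / pk


def _draw(rng, spec):
    """Draw one value from a distribution spec.

    Specs: number (fixed), ("normal", mean, sd), ("lognormal", mean, sd of log),
    ("mixture", [(weight, spec), ...]).
    """
    if isinstance(spec, (int, float)):
        return float(spec)
    kind = spec[0]
    if kind == "normal":
        return float(rng.normal(spec[1], spec[2]))
    if kind == "lognormal":
        return float(rng.lognormal(spec[1], spec[2]))
    if kind == "mixture":
        weights = np.array([w for w, _ in spec[1]])
        k = rng.choice(len(spec[1]), p=weights / weights.sum())
        return _draw(rng, spec[1][k][1])
    raise ValueError(f"unknown distribution spec {spec!r}")


@dataclass(frozen=True)
class EventSpec:
    """Unitary synaptic event statistics for one connection."""

    latency: object = 0.84         # ms; distribution spec
    amplitude: object = 155.0      # pA (PSC) or mV (EPSP) magnitude
    tau_rise: float = 0.45         # ms
    tau_decay: float = 6.0         # ms
    failure_rate: float = 0.05

    def __post_init__(self):
        if not 0.0 <= self.failure_rate <= 1.0:
            raise ValueError("failure_rate must be in [0, 1]")


@dataclass(frozen=True)
class TrainSpec:
    """Presynaptic AP train: ``n_pulses`` APs at ``rate_hz``."""

    n_pulses: int = 8
    rate_hz: float = 5.0
    first_ap: float = 20.0         # ms


def gen_connection_traces(kind: str = "psc", event: EventSpec = EventSpec(),
                          train: TrainSpec = TrainSpec(), dt: float = 0.02,
                          noise_sd: float = 0.0, seed: int = 0):
    """Paired pre/post traces with unitary synaptic events of known statistics.

    ``kind`` is ``"psc"`` (postsynaptic current, negative pA events; the
    FSIN-to-pyramidal configuration) or ``"epsp"`` (postsynaptic potential,
    positive mV events; pyramidal-to-FSIN).  Returns
    ``(pre_trace, post_trace, ground_truth)`` where the ground truth carries
    the per-event latency/amplitude/failure table.
    """
    if kind not in ("psc", "epsp"):
        raise ValueError(f"kind must be 'psc' or 'epsp', got {kind!r}")
    rng = np.random.default_rng(seed)
    ap_times = train.first_ap + np.arange(train.n_pulses) * 1e3 / train.rate_hz
    duration = ap_times[-1] + 60.0
    t = np.arange(0.0, duration, dt)

    # stereotyped presynaptic AP: triangular spike on a flat baseline
    pre = np.full(t.size, -65.0)
    for ta in ap_times:
        rise = (t >= ta - 0.5) & (t < ta)
        fall = (t >= ta) & (t < ta + 1.0)
        pre[rise] = -65.0 + (30.0 - (-65.0)) * (t[rise] - (ta - 0.5)) / 0.5
        pre[fall] = 30.0 + (-65.0 - 30.0) * (t[fall] - ta) / 1.0

    sign = -1.0 if kind == "psc" else 1.0
    base = 0.0 if kind == "psc" else -70.0
    post = np.full(t.size, base)
    rows = []
    for ta in ap_times:
        fail = bool(rng.random() < event.failure_rate)
        lat = abs(_draw(rng, event.latency))
        amp = abs(_draw(rng, event.amplitude))
        if not fail:
            onset = ta + lat
            sel = t >= onset
            post[sel] += sign * amp * _dual_exp(t[sel] - onset,
                                                event.tau_rise, event.tau_decay)
        rows.append({"ap_time": float(ta), "latency": lat, "amplitude": amp,
                     "failure": fail})
    if noise_sd > 0:
        post = post + rng.normal(0.0, noise_sd, post.size)
    units = "pA" if kind == "psc" else "mV"
    gt = GroundTruth("gen_connection_traces",
                     {"kind": kind, "events": rows, "noise_sd": noise_sd,
                      "tau_rise": event.tau_rise, "tau_decay": event.tau_decay,
                      "failure_rate": event.failure_rate}, seed)
    return (Trace(pre, dt, site="pre", units="mV"),
            Trace(post, dt, site="post", units=units), gt)


# ---------------------------------------------------------------------------
# Test morphologies
# ---------------------------------------------------------------------------

def gen_test_morphologies(params: MorphoParams, n_trees: int = 1,
                          jitter_sd: float = 0.0, cut_fraction: float = 0.0,
                          seed: int = 0):
    """Morphologies with optional segment-length jitter and cut terminals.

    Trees come from :func:`fsin.morphology.generate_morphology`; with
    ``jitter_sd`` > 0 each segment length is scaled by a truncated normal
    factor, and ``cut_fraction`` of the terminal segments are truncated to a
    random fraction of their length and annotated as cut terminals.  Returns a
    list of ``(tree, ground_truth)`` pairs; each ground truth records the
    jittered segment lengths and the cut-tip annotations.
    """
    if not 0.0 <= cut_fraction < 1.0:
        raise ValueError("cut_fraction must be in [0, 1)")
    out = []
    for k in range(n_trees):
        rng = np.random.default_rng([seed, k])
        lengths = {}

        def seg_len(dend, order, j):
            key = (dend, order, j)
            if key not in lengths:
                base = (params.terminal_len if order == params.terminal_order
                        else params.nonterminal_len)
                f = max(0.2, 1.0 + rng.normal(0.0, jitter_sd)) if jitter_sd > 0 else 1.0
                lengths[key] = base * f
            return lengths[key]

        tree = generate_morphology(params, geometry_seed=seed + k,
                                   segment_length_fn=seg_len)
        full_tree = tree.copy()
        cut_tips = []
        if cut_fraction > 0:
            tree, cut_tips = _truncate_terminals(tree, cut_fraction, rng)
        gt = GroundTruth("gen_test_morphologies",
                         {"params": asdict(params), "jitter_sd": jitter_sd,
                          "cut_fraction": cut_fraction,
                          "segment_lengths": {str(k_): v for k_, v in lengths.items()},
                          "cut_tip_count": len(cut_tips)}, seed)
        gt.params["full_tree"] = full_tree
        out.append((tree, gt))
    return out


def _truncate_terminals(tree: NeuronTree, fraction: float, rng):
    """Truncate a random fraction of terminal dendritic segments, flagging the
    new tips as cut."""
    segs = tree.segments(DEND)
    ch = tree.children()
    term_segs = [s for s in segs if not ch[s[-1]]]
    n_cut = max(1, int(round(fraction * len(term_segs))))
    chosen = rng.choice(len(term_segs), size=n_cut, replace=False)
    L = tree.edge_lengths()
    drop = np.zeros(len(tree), bool)
    new_tips = []
    for ci in chosen:
        seg = term_segs[ci]
        arc = np.cumsum([L[i] for i in seg[1:]])
        keep_len = float(rng.uniform(0.3, 0.8)) * arc[-1]
        keep_nodes = [seg[0]] + [n for n, a in zip(seg[1:], arc) if a <= keep_len]
        if len(keep_nodes) < 2:
            keep_nodes = seg[:2]
        for n_ in seg[1:]:
            if n_ not in keep_nodes:
                drop[n_] = True
        new_tips.append(keep_nodes[-1])
    keep = ~drop
    remap = -np.ones(len(tree), dtype=np.int64)
    remap[keep] = np.arange(keep.sum())
    parent = np.where(tree.parent >= 0, remap[tree.parent], -1)[keep]
    cut = tree.cut.copy()
    cut[new_tips] = True
    new_tree = NeuronTree(tree.struct[keep], tree.xyz[keep], tree.radius[keep],
                          parent, cut[keep])
    return new_tree, [int(remap[i]) for i in new_tips]
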