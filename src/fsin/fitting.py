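"""Feature-objective model fitting.

The 13 free parameters of the cable model (four conductance densities in each
of dendrite/soma/axon plus the axonal Na+ voltage shift) are optimized against
a catalogue of electrophysiological feature objectives measured under four
stimulation protocols:

* 100 ms, +200 pA somatic step (firing pattern and AP1 waveform),
* 100 ms, -100 pA somatic step (passive deflection, decay τ, sag),
* 4 ms, +800 pA somatic pulse (AP initiation timing at soma/AIS/distal axon),
* simultaneous activation of four dendritic synapses 108 µm from the soma.

Each objective contributes |feature - target| / SD to the fitness; a feature
that is undefined (e.g. a spike-timing feature of a model that does not spike)
incurs a fixed penalty of 250.  Optimization uses a bounded real-coded
evolutionary algorithm with simulated-binary crossover and polynomial mutation
(both with distribution index eta), binary-tournament parent selection and
elitist (mu + lambda) survivor selection.

Sign conventions for timing differences: ``pulse_ais_soma_lead`` is
t_first_spike(soma) - t_first_spike(AIS), positive when the AP initiates in
the AIS before the soma; ``pulse_distal_soma_lag`` is
t_first_spike(distal axon) - t_first_spike(soma), positive because the distal
axon fires after the soma under somatic stimulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cable import (CellModel, ChannelDensities, PARAM_NAMES, StepStim,
                    SynapseSpec, simulate)
from .ephys import ap_waveform_features, detect_aps, passive_features
from .traceio import Trace

UNDEFINED_PENALTY = 250.0


@dataclass(frozen=True)
class FeatureObjective:
    name: str
    protocol: str
    target: float
    sd: float

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("objective SD must be positive")


def reference_objectives() -> list:
    """The catalogue of feature objectives used for model optimization."""
    rows = [
        # 100 ms, 200 pA step
        ("t_first_spike_step", "step200", 10.0, 1.0),
        ("ap1_peak", "step200", 30.0, 5.0),
        ("ap1_half_width", "step200", 0.3, 0.05),
        ("ap1_rise_speed", "step200", 350.0, 70.0),
        ("ap1_fall_speed", "step200", -180.0, 40.0),
        ("ahp", "step200", -60.0, 10.0),
        ("spike_count_step", "step200", 10.0, 5.0),
        ("ap1_ap2_peak_diff", "step200", 0.0, 4.0),
        # 100 ms, -100 pA step
        ("deflection", "stepm100", 10.0, 3.0),
        ("decay_tau", "stepm100", 12.0, 4.0),
        ("sag_ratio", "stepm100", 0.1, 0.04),
        # 800 pA, 4 ms pulse
        ("pulse_spike_count_soma", "pulse800", 1.0, 0.0001),
        ("pulse_spike_count_ais", "pulse800", 1.0, 0.0001),
        ("pulse_spike_count_distal", "pulse800", 1.0, 0.0001),
        ("pulse_t_first_soma", "pulse800", 2.9, 0.1),
        ("pulse_ais_soma_lead", "pulse800", 0.05, 0.005),
        ("pulse_distal_soma_lag", "pulse800", 0.45, 0.15),
        # synapse activation: 4 x 10 nS at 108 µm from soma
        ("syn_spike_count_soma", "synapse", 1.0, 0.0001),
        ("syn_spike_count_ais", "synapse", 1.0, 0.0001),
        ("syn_ais_soma_lead", "synapse", 0.05, 0.005),
    ]
    return [FeatureObjective(n, p, t, s) for n, p, t, s in rows]


def load_objectives(path) -> list:
    """Load objectives from a CSV with columns name,protocol,target,sd."""
    df = pd.read_csv(path)
    return [FeatureObjective(r["name"], r["protocol"], float(r["target"]),
                             float(r["sd"])) for _, r in df.iterrows()]


def save_objectives(objectives, path) -> None:
    pd.DataFrame([{"name": o.name, "protocol": o.protocol, "target": o.target,
                   "sd": o.sd} for o in objectives]).to_csv(path, index=False)


@dataclass
class FeatureVector:
    """Extracted feature values plus their provenance (protocol, site)."""

    values: dict
    provenance: dict = field(default_factory=dict)

    def __getitem__(self, name):
        return self.values[name]

    def __contains__(self, name):
        return name in self.values


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------

SYN_PROTOCOL_DISTANCE = 108.0   # µm from soma
SYN_PROTOCOL_GMAX = 10.0        # nS each (0.01 µS), 4 synapses
SYN_PROTOCOL_N = 4


def protocol_specs(fast: bool = False) -> dict:
    """Stimulation/recording protocol definitions.

    ``fast`` selects the coarser time steps used inside the optimization loop;
    the default resolution (2 µs for AP-timing protocols) is used for final
    feature evaluation.
    """
    dt_ap = 0.01 if fast else 0.002
    dt_step = 0.01 if fast else 0.005
    return {
        "step200": dict(stims=[StepStim(200.0, 10.0, 100.0)], synapses=[],
                        record=("soma",), dt=dt_step, t_stop=112.0, onset=10.0),
        "stepm100": dict(stims=[StepStim(-100.0, 10.0, 100.0)], synapses=[],
                         record=("soma",), dt=0.025, t_stop=175.0, onset=10.0),
        "pulse800": dict(stims=[StepStim(800.0, 2.0, 4.0)], synapses=[],
                         record=("soma", "AIS", "distal_axon"), dt=dt_ap,
                         t_stop=14.0, onset=2.0),
        "synapse": dict(
            stims=[],
            synapses=[SynapseSpec((SYN_PROTOCOL_DISTANCE, b), SYN_PROTOCOL_GMAX, 2.0)
                      for b in range(SYN_PROTOCOL_N)],
            record=("soma", "AIS"), dt=dt_ap, t_stop=14.0, onset=2.0),
    }


def run_fitting_protocols(cell: CellModel, fast: bool = False) -> dict:
    """Simulate all fitting protocols; returns {protocol: {site: Trace}}."""
    out = {}
    for pid, spec in protocol_specs(fast).items():
        out[pid] = simulate(cell, stims=spec["stims"], synapses=spec["synapses"],
                            record_sites=spec["record"], dt=spec["dt"],
                            t_stop=spec["t_stop"])
    return out


def first_spike_time(trace: Trace, onset: float):
    """Time from ``onset`` to the first AP peak (parabolic peak refinement)."""
    peaks = detect_aps(trace)
    peaks = peaks[peaks >= onset]
    if peaks.size == 0:
        return None
    i = trace.index_at(peaks[0])
    if 0 < i < trace.y.size - 1:
        y0, y1, y2 = trace.y[i - 1:i + 2]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            frac = 0.5 * (y0 - y2) / denom
            return float(trace.t0 + (i + frac) * trace.dt - onset)
    return float(peaks[0] - onset)


def extract_model_features(traces: dict, fast: bool = False) -> FeatureVector:
    """Extract the full objective-feature catalogue from protocol traces.

    ``traces`` maps protocol id to ``{site: Trace}`` as produced by
    :func:`run_fitting_protocols`.  Spike-timing features of non-spiking
    responses are left out of the vector (scored as undefined).
    """
    specs = protocol_specs(fast)
    vals, prov = {}, {}

    def put(name, value, pid, site):
        if value is not None and np.isfinite(value):
            vals[name] = float(value)
            prov[name] = (pid, site)

    # --- 200 pA step
    pid = "step200"
    onset = specs[pid]["onset"]
    tr = _get_site(traces, pid, "soma")
    peaks = detect_aps(tr)
    stim_end = onset + 100.0
    peaks_in = peaks[(peaks >= onset) & (peaks <= stim_end)]
    put("spike_count_step", float(peaks_in.size), pid, "soma")
    if peaks_in.size:
        put("t_first_spike_step", first_spike_time(tr, onset), pid, "soma")
        apf = ap_waveform_features(tr, peaks_in[0], window_pre=min(8.0, peaks_in[0] - 1.0),
                                   window_post=3.0, target_dt=tr.dt)
        put("ap1_peak", apf.peak, pid, "soma")
        put("ap1_half_width", apf.half_width, pid, "soma")
        put("ap1_rise_speed", apf.rise_speed, pid, "soma")
        put("ap1_fall_speed", apf.fall_speed, pid, "soma")
        i_last = tr.index_at(peaks_in[-1])
        i_end = tr.index_at(stim_end)
        if i_end > i_last:
            put("ahp", float(tr.y[i_last:i_end].min()), pid, "soma")
        if peaks_in.size >= 2:
            p1 = tr.y[tr.index_at(peaks_in[0])]
            p2 = tr.y[tr.index_at(peaks_in[1])]
            put("ap1_ap2_peak_diff", float(p1 - p2), pid, "soma")

    # --- -100 pA step
    pid = "stepm100"
    tr = _get_site(traces, pid, "soma")
    try:
        pf = passive_features(tr, specs[pid]["onset"], 100.0, -100.0)
        put("deflection", pf["deflection"], pid, "soma")
        put("decay_tau", pf["decay_tau"], pid, "soma")
        put("sag_ratio", pf["sag_ratio"], pid, "soma")
    except ValueError:
        pass  # spiking during the hyperpolarizing step: features undefined

    # --- 800 pA, 4 ms pulse
    pid = "pulse800"
    onset = specs[pid]["onset"]
    times = {}
    for site, short in (("soma", "soma"), ("AIS", "ais"), ("distal_axon", "distal")):
        tr = _get_site(traces, pid, site)
        n = detect_aps(tr).size
        put(f"pulse_spike_count_{short}", float(n), pid, site)
        times[short] = first_spike_time(tr, onset)
    if times["soma"] is not None:
        put("pulse_t_first_soma", times["soma"], pid, "soma")
        if times["ais"] is not None:
            put("pulse_ais_soma_lead", times["soma"] - times["ais"], pid, "AIS")
        if times["distal"] is not None:
            put("pulse_distal_soma_lag", times["distal"] - times["soma"], pid,
                "distal_axon")

    # --- synapse activation
    pid = "synapse"
    onset = specs[pid]["onset"]
    t_soma = first_spike_time(_get_site(traces, pid, "soma"), onset)
    t_ais = first_spike_time(_get_site(traces, pid, "AIS"), onset)
    put("syn_spike_count_soma",
        float(detect_aps(_get_site(traces, pid, "soma")).size), pid, "soma")
    put("syn_spike_count_ais",
        float(detect_aps(_get_site(traces, pid, "AIS")).size), pid, "AIS")
    if t_soma is not None and t_ais is not None:
        put("syn_ais_soma_lead", t_soma - t_ais, pid, "AIS")
    return FeatureVector(vals, prov)


def _get_site(traces, pid, site):
    if pid not in traces or site not in traces[pid]:
        raise KeyError(f"missing recording {site!r} for protocol {pid!r}")
    return traces[pid][site]


# ---------------------------------------------------------------------------
# Fitness
# ---------------------------------------------------------------------------

def evaluate_fitness(fv: FeatureVector | None, objectives) -> dict:
    """SD-scaled objective scores: |feature - target| / SD per objective.

    Undefined features (and a failed simulation, ``fv is None``) are scored
    with the fixed penalty.  Returns per-objective scores plus ``"total"``.
    """
    scores = {}
    for obj in objectives:
        if fv is not None and obj.name in fv:
            scores[obj.name] = abs(fv[obj.name] - obj.target) / obj.sd
        else:
            scores[obj.name] = UNDEFINED_PENALTY
    scores["total"] = float(sum(scores.values()))
    return scores


def make_evaluator(cell: CellModel, fast: bool = True):
    """Closure evaluating a parameter vector on ``cell``'s morphology."""

    def evaluate(x) -> FeatureVector | None:
        try:
            densities = ChannelDensities.from_vector(x)
            traces = run_fitting_protocols(cell.with_densities(densities), fast=fast)
            return extract_model_features(traces, fast=fast)
        except (FloatingPointError, ValueError):
            return None

    return evaluate


# ---------------------------------------------------------------------------
# Evolutionary optimization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamSpace:
    """Bounded search space over the 13 free parameters."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lo, up = np.asarray(self.lower, float), np.asarray(self.upper, float)
        if lo.shape != (len(PARAM_NAMES),) or up.shape != (len(PARAM_NAMES),):
            raise ValueError(f"bounds must have length {len(PARAM_NAMES)}")
        if not np.all(np.isfinite(lo)) or not np.all(np.isfinite(up)):
            raise ValueError("bounds must be finite")
        if np.any(lo >= up):
            raise ValueError("lower bounds must be below upper bounds")
        if np.any(lo[:-1] < 0):
            raise ValueError("density bounds must be non-negative")

    @classmethod
    def around_reference(cls, reference: ChannelDensities, factor: float = 10.0):
        """Default space: [0, factor x reference] per density; the (negative)
        axonal shift spans [factor x reference, 0]."""
        ref = reference.to_vector()
        lo = np.zeros(ref.size)
        up = factor * ref
        lo[-1], up[-1] = factor * ref[-1], 0.0
        return cls(lo, up)


@dataclass(frozen=True)
class EAConfig:
    n_generations: int = 500
    offspring_size: int = 100
    eta: float = 10.0
    cxpb: float = 0.7
    mutpb: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.cxpb <= 1 and 0 <= self.mutpb <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_generations < 1 or self.offspring_size < 1:
            raise ValueError("sizes must be >= 1")


def _sbx(rng, a, b, lo, up, eta):
    """Simulated binary crossover (per-gene, bounded)."""
    c1, c2 = a.copy(), b.copy()
    for i in range(a.size):
        if rng.random() > 0.5 or abs(a[i] - b[i]) < 1e-14:
            continue
        x1, x2 = min(a[i], b[i]), max(a[i], b[i])
        u = rng.random()
        beta = 1.0 + 2.0 * (x1 - lo[i]) / (x2 - x1)
        alpha = 2.0 - beta ** -(eta + 1.0)
        bq = ((u * alpha) ** (1.0 / (eta + 1.0)) if u <= 1.0 / alpha
              else (1.0 / (2.0 - u * alpha)) ** (1.0 / (eta + 1.0)))
        y1 = 0.5 * ((x1 + x2) - bq * (x2 - x1))
        beta = 1.0 + 2.0 * (up[i] - x2) / (x2 - x1)
        alpha = 2.0 - beta ** -(eta + 1.0)
        bq = ((u * alpha) ** (1.0 / (eta + 1.0)) if u <= 1.0 / alpha
              else (1.0 / (2.0 - u * alpha)) ** (1.0 / (eta + 1.0)))
        y2 = 0.5 * ((x1 + x2) + bq * (x2 - x1))
        c1[i], c2[i] = np.clip([y1, y2], lo[i], up[i])
    return c1, c2


def _poly_mutate(rng, x, lo, up, eta, indpb):
    """Bounded polynomial mutation (per-gene probability ``indpb``)."""
    y = x.copy()
    for i in range(x.size):
        if rng.random() >= indpb:
            continue
        span = up[i] - lo[i]
        d1 = (y[i] - lo[i]) / span
        d2 = (up[i] - y[i]) / span
        u = rng.random()
        mp = 1.0 / (eta + 1.0)
        if u < 0.5:
            val = 2.0 * u + (1.0 - 2.0 * u) * (1.0 - d1) ** (eta + 1.0)
            dq = val ** mp - 1.0
        else:
            val = 2.0 * (1.0 - u) + 2.0 * (u - 0.5) * (1.0 - d2) ** (eta + 1.0)
            dq = 1.0 - val ** mp
        y[i] = np.clip(y[i] + dq * span, lo[i], up[i])
    return y


@dataclass
class OptimizeResult:
    best: ChannelDensities
    best_score: float
    best_features: FeatureVector | None
    log: pd.DataFrame
    history: list


def optimize(space: ParamSpace, objectives, ea: EAConfig, evaluator,
             seed_individuals=(), mut_indpb: float = 0.3,
             callback=None) -> OptimizeResult:
    """Minimize the total SD-scaled deviation over the bounded parameter space.

    ``evaluator`` maps a parameter vector to a :class:`FeatureVector` (or
    ``None`` on simulation failure, which is penalized and the run continues).
    ``seed_individuals`` (parameter vectors or :class:`ChannelDensities`) are
    injected into the initial population, clipped to bounds.  The run is fully
    reproducible from ``ea.seed``; the log records per-generation best/mean.
    """
    rng = np.random.default_rng(ea.seed)
    lo, up = space.lower, space.upper
    n = lo.size
    pop = rng.uniform(lo, up, size=(ea.offspring_size, n))
    for k, ind in enumerate(seed_individuals):
        if k >= ea.offspring_size:
            break
        vec = ind.to_vector() if hasattr(ind, "to_vector") else np.asarray(ind, float)
        pop[k] = np.clip(vec, lo, up)

    def score_all(mat):
        fvs = [evaluator(x) for x in mat]
        tots = np.array([evaluate_fitness(fv, objectives)["total"] for fv in fvs])
        return fvs, tots

    fvs, scores = score_all(pop)
    rows, history = [], []
    for gen in range(ea.n_generations):
        # binary-tournament parent selection
        idx = rng.integers(0, ea.offspring_size, size=(ea.offspring_size, 2))
        parents = np.where((scores[idx[:, 0]] <= scores[idx[:, 1]])[:, None],
                           pop[idx[:, 0]], pop[idx[:, 1]])
        children = parents.copy()
        for i in range(0, ea.offspring_size - 1, 2):
            if rng.random() < ea.cxpb:
                children[i], children[i + 1] = _sbx(rng, children[i],
                                                    children[i + 1], lo, up, ea.eta)
        for i in range(ea.offspring_size):
            if rng.random() < ea.mutpb:
                children[i] = _poly_mutate(rng, children[i], lo, up, ea.eta,
                                           mut_indpb)
        c_fvs, c_scores = score_all(children)
        # elitist (mu + lambda) survivor selection
        allpop = np.vstack([pop, children])
        allscores = np.concatenate([scores, c_scores])
        allfvs = fvs + c_fvs
        order = np.argsort(allscores, kind="stable")[:ea.offspring_size]
        pop, scores = allpop[order], allscores[order]
        fvs = [allfvs[i] for i in order]
        rows.append({"generation": gen, "best": float(scores.min()),
                     "mean": float(scores.mean())})
        history.append(pop[0].copy())
        if callback is not None:
            callback(gen, scores, pop)
    best = int(np.argmin(scores))
    return OptimizeResult(ChannelDensities.from_vector(pop[best]),
                          float(scores[best]), fvs[best],
                          pd.DataFrame(rows), history)
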