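"""In-silico single-cell experiments.

Reproduces the model experiments of the study design: somatic EPSP amplitude
and rise time as a function of synapse distance (dendritic filtering), random
multi-synapse configurations, candidate EPSP "boost" mechanisms (doubled
synaptic strength, HCN or leak conductance gradients, stretched conductance),
AP-delay scans under suprathreshold synaptic drive, dendritic-scaling effects
on AP threshold / onset rapidity / AIS lead, and the arithmetic composition of
the disynaptic inhibition delay from its stage delays.

All experiments are pure functions of (cell specification, protocol, seed) and
return tidy :class:`pandas.DataFrame` records inside an
:class:`ExperimentResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cable import (BiophysConstants, CellModel, ChannelDensities, StepStim,
                    SynapseSpec, build_cell, epsp_metrics, simulate)
from .ephys import ap_waveform_features, detect_aps
from .fitting import first_spike_time
from .morphology import NeuronTree, scale_dendrites


@dataclass
class ExperimentResult:
    condition: str
    records: pd.DataFrame
    seed: int | None = None


@dataclass(frozen=True)
class CellSpec:
    """Declarative cell specification that experiments can transform.

    ``syn_gain`` multiplies every synaptic conductance used on this cell;
    ``dend_gradients`` maps channel names to linear path-distance multiplier
    slopes; ``stretched`` redistributes dendritic conductance distally at a
    constant total.
    """

    tree: NeuronTree
    densities: ChannelDensities
    constants: BiophysConstants = BiophysConstants()
    syn_gain: float = 1.0
    dend_gradients: tuple = ()
    stretched: bool = False
    max_seg_len: float = 25.0

    def build(self) -> CellModel:
        return build_cell(self.tree, self.densities, self.constants,
                          max_seg_len=self.max_seg_len,
                          dend_gradients=dict(self.dend_gradients),
                          stretched=self.stretched)


BOOST_MECHANISMS = ("synapse_x2", "ih_gradient", "leak_gradient",
                    "stretched_conductance")


def apply_boost_mechanism(spec: CellSpec, mechanism: str,
                          gradient_slope: float = 2.0) -> CellSpec:
    """Return a cell spec with one EPSP-boost mechanism applied.

    ``synapse_x2`` doubles every synaptic conductance; ``ih_gradient`` /
    ``leak_gradient`` add a linear distance-dependent multiplier
    ``g(x) = g0 (1 + s x / x_max)`` to the dendritic HCN / leak density;
    ``stretched_conductance`` redistributes all dendritic conductance toward
    the distal arbor at constant total conductance.
    """
    if mechanism == "synapse_x2":
        return replace(spec, syn_gain=spec.syn_gain * 2.0)
    if mechanism == "ih_gradient":
        return replace(spec, dend_gradients=spec.dend_gradients
                       + (("hcn", gradient_slope),))
    if mechanism == "leak_gradient":
        return replace(spec, dend_gradients=spec.dend_gradients
                       + (("leak", gradient_slope),))
    if mechanism == "stretched_conductance":
        return replace(spec, stretched=True)
    raise ValueError(f"unknown boost mechanism {mechanism!r}; "
                     f"choose from {BOOST_MECHANISMS}")


# ---------------------------------------------------------------------------
# EPSP filtering experiments
# ---------------------------------------------------------------------------

def epsp_distance_scan(spec: CellSpec | CellModel, distances, g_syn: float = 0.5,
                       branch: int = 0, dt: float = 0.025, t_stop: float = 60.0,
                       onset: float = 5.0, condition: str = "") -> ExperimentResult:
    """Somatic EPSP metrics for a single synapse at each dendritic distance."""
    cell, gain = _as_cell(spec)
    rows = []
    for dist in distances:
        comp = cell.locate_dendrite(float(dist), branch)
        tr = simulate(cell, synapses=[SynapseSpec(comp, g_syn * gain, onset)],
                      record_sites=("soma",), dt=dt, t_stop=t_stop)["soma"]
        met = epsp_metrics(tr, onset) or {}
        rows.append({"distance": float(dist),
                     "amplitude": met.get("amplitude", np.nan),
                     "rise_time": met.get("rise_time_10_90", np.nan),
                     "onset_latency": met.get("onset_latency", np.nan),
                     "decay_tau": met.get("decay_tau", np.nan)})
    return ExperimentResult(condition or "epsp_distance_scan", pd.DataFrame(rows))


def random_synapse_experiment(spec: CellSpec | CellModel, n_configs: int = 20,
                              n_syn: int = 10, g_syn: float = 0.5, seed: int = 0,
                              dt: float = 0.025, t_stop: float = 60.0,
                              onset: float = 5.0,
                              condition: str = "") -> ExperimentResult:
    """Compound somatic EPSPs from random dendritic synapse configurations.

    Each configuration activates ``n_syn`` synapses simultaneously at locations
    sampled uniformly over total dendritic cable length (seed-reproducible).
    """
    cell, gain = _as_cell(spec)
    rng = np.random.default_rng(seed)
    rows = []
    for cfg in range(n_configs):
        us = rng.random(n_syn)
        comps = [cell.dendrite_position_at_cable_fraction(u) for u in us]
        syns = [SynapseSpec(c, g_syn * gain, onset) for c in comps]
        tr = simulate(cell, synapses=syns, record_sites=("soma",), dt=dt,
                      t_stop=t_stop)["soma"]
        met = epsp_metrics(tr, onset) or {}
        rows.append({"config": cfg,
                     "amplitude": met.get("amplitude", np.nan),
                     "rise_time": met.get("rise_time_10_90", np.nan),
                     "mean_distance": float(np.mean(cell.middist[comps]))})
    return ExperimentResult(condition or "random_synapse", pd.DataFrame(rows),
                            seed=seed)


# ---------------------------------------------------------------------------
# AP timing experiments
# ---------------------------------------------------------------------------

def ap_delay_scan(spec: CellSpec | CellModel, n_sites: int = 20,
                  g_syn: float = 3.0, n_syn: int = 20,
                  random_sites: bool = False, seed: int = 0,
                  dt: float = 0.01, t_stop: float = 40.0,
                  onset: float = 2.0, condition: str = "") -> ExperimentResult:
    """Delay from synapse activation to the somatic AP peak per input distance.

    For each of ``n_sites`` graded path distances, ``n_syn`` synapses of
    ``g_syn`` each are activated simultaneously, spread over the distinct
    dendritic branches passing through that distance (a single dendritic site
    saturates at the synaptic reversal potential and cannot fire the cell from
    distal locations, so suprathreshold drive must be distributed).  With
    ``random_sites`` the synapse cohort is instead drawn uniformly over the
    arbor around each sampled distance.  Distances whose cohort fails to
    trigger an AP are recorded with NaN delay and counted via the ``spiked``
    column.
    """
    cell, gain = _as_cell(spec)
    rng = np.random.default_rng(seed)
    max_d = cell.max_dendrite_path
    rows = []
    for k in range(n_sites):
        if random_sites:
            dist = float(rng.uniform(0.05, 0.95) * max_d)
        else:
            dist = float(np.linspace(0.05, 0.95, n_sites)[k] * max_d)
        comps = cell.comps_at_distance(min(dist, max_d * 0.99))
        sites = [comps[i % len(comps)] for i in range(n_syn)]
        syns = [SynapseSpec(c, g_syn * gain, onset) for c in sites]
        tr = simulate(cell, synapses=syns, record_sites=("soma",), dt=dt,
                      t_stop=t_stop)["soma"]
        delay = first_spike_time(tr, onset)
        rows.append({"distance": dist,
                     "ap_delay": np.nan if delay is None else delay,
                     "spiked": delay is not None})
    df = pd.DataFrame(rows).sort_values("distance", ignore_index=True)
    return ExperimentResult(condition or "ap_delay_scan", df, seed=seed)


def _branch_max_distance(cell: CellModel, branch: int) -> float:
    d = 0.0
    while True:
        try:
            comp = cell.locate_dendrite(d + 10.0, branch)
        except ValueError:
            return d
        d = cell.middist[comp] + cell.length[comp] / 2


def find_suprathreshold_gsyn(specs, start: float = 1.0, factor: float = 1.25,
                             max_g: float = 200.0) -> float:
    """Smallest synaptic conductance (geometric grid) that triggers a somatic AP
    from the most distal dendritic site in every supplied model."""
    g = start
    while g <= max_g:
        ok = True
        for spec in specs:
            cell, gain = _as_cell(spec)
            max_d = cell.max_dendrite_path * 0.95
            comp = cell.locate_dendrite(max_d, 0)
            tr = simulate(cell, synapses=[SynapseSpec(comp, g * gain, 2.0)],
                          record_sites=("soma",), dt=0.01, t_stop=40.0)["soma"]
            if detect_aps(tr).size == 0:
                ok = False
                break
        if ok:
            return g
        g *= factor
    raise ValueError(f"no conductance up to {max_g} nS triggers APs in all models")


def dendritic_scaling_experiment(tree: NeuronTree, densities: ChannelDensities,
                                 scales=(0.5, 1.0, 1.5),
                                 constants: BiophysConstants = BiophysConstants(),
                                 pulse: StepStim = StepStim(800.0, 2.0, 4.0),
                                 dt: float = 0.002, t_stop: float = 14.0,
                                 max_seg_len: float = 25.0) -> ExperimentResult:
    """AP threshold, onset rapidity and AIS-soma lead vs dendritic length scale.

    Each scaled model receives the identical somatic short pulse; AP waveform
    features are measured at the soma and first-spike times at soma and AIS.
    Raises if the pulse is subthreshold at any scale (increase the stimulus).
    """
    rows = []
    for s in scales:
        cell = build_cell(scale_dendrites(tree, float(s)), densities, constants,
                          max_seg_len=max_seg_len)
        traces = simulate(cell, stims=[pulse], record_sites=("soma", "AIS"),
                          dt=dt, t_stop=t_stop)
        t_soma = first_spike_time(traces["soma"], pulse.onset)
        t_ais = first_spike_time(traces["AIS"], pulse.onset)
        if t_soma is None or t_ais is None:
            raise ValueError(f"pulse subthreshold at dendritic scale {s}; "
                             "raise the stimulus amplitude")
        peaks = detect_aps(traces["soma"])
        apf = ap_waveform_features(traces["soma"], peaks[0],
                                   window_pre=min(5.0, peaks[0] - 0.5),
                                   window_post=3.0, target_dt=dt)
        rows.append({"scale": float(s), "ap_threshold": apf.threshold,
                     "onset_rapidity": apf.onset_rapidity,
                     "ais_soma_lead": t_soma - t_ais})
    return ExperimentResult("dendritic_scaling", pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Disynaptic delay composition
# ---------------------------------------------------------------------------

def compose_disynaptic_delay(stage_delays) -> float:
    """Total disynaptic-inhibition delay as the sum of its stage delays.

    The stages are the excitatory synaptic onset latency, the dendritic EPSP
    transfer delay, the AIS-vs-soma AP timing contribution, and the inhibitory
    output latency.  Empty input composes to 0.
    """
    total = 0.0
    for d in stage_delays:
        if d < 0:
            raise ValueError(f"stage delay must be non-negative, got {d}")
        total += float(d)
    return total


def _as_cell(spec):
    if isinstance(spec, CellSpec):
        return spec.build(), spec.syn_gain
    return spec, 1.0
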