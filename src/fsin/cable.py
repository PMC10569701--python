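"""Compartmental FSIN model: discretization, simulation, EPSP metrics.

A :class:`~fsin.morphology.NeuronTree` is discretized into cylindrical
compartments (one per <= ``max_seg_len`` of cable).  The membrane carries four
conductances per region (dendrite / soma / axon): transient Na+, delayed
rectifier K+, HCN and passive leak; gating kinetics live in
:mod:`fsin.channels`.  Voltage is integrated with an implicit theta-method on
the branched cable (Hines-ordered direct solve, see :mod:`fsin._kernel`).

Unit system: mV, ms, µm, pA, nS, pS/µm² (densities), µF/cm² (capacitance),
Ω·cm (axial resistivity).  Conversions are centralized here:
``1 pS/µm² * µm² = 1e-3 nS``; ``1 µF/cm² * µm² = 0.01 pF``;
``Ω·cm = 1e4 Ω·µm``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import channels as _ch
from ._kernel import integrate, STATUS_OK
from .morphology import AXON, DEND, SOMA, NeuronTree
from .traceio import Trace

REGION_DEND, REGION_SOMA, REGION_AXON = 0, 1, 2
_REGION_OF_STRUCT = {DEND: REGION_DEND, SOMA: REGION_SOMA, AXON: REGION_AXON}


@dataclass(frozen=True)
class BiophysConstants:
    """Fixed biophysical constants (non-fitted)."""

    cm: float = 0.9        # specific capacitance, µF/cm²
    ra: float = 100.0      # axial resistivity, Ω·cm
    e_leak: float = -75.0  # mV
    e_na: float = 64.0     # mV
    e_k: float = -85.0     # mV
    e_hcn: float = -45.0   # mV

    def __post_init__(self):
        if self.cm <= 0 or self.ra <= 0:
            raise ValueError("cm and ra must be positive")


PARAM_NAMES = (
    "g_leak_dend", "g_leak_soma", "g_leak_axon",
    "g_na_dend", "g_na_soma", "g_na_axon",
    "g_k_dend", "g_k_soma", "g_k_axon",
    "g_hcn_dend", "g_hcn_soma", "g_hcn_axon",
    "axon_na_vshift",
)


@dataclass(frozen=True)
class ChannelDensities:
    """The 13 free parameters: 4 conductance densities x 3 regions (pS/µm²)
    plus the axonal Na+ gating voltage shift (mV)."""

    g_leak_dend: float
    g_leak_soma: float
    g_leak_axon: float
    g_na_dend: float
    g_na_soma: float
    g_na_axon: float
    g_k_dend: float
    g_k_soma: float
    g_k_axon: float
    g_hcn_dend: float
    g_hcn_soma: float
    g_hcn_axon: float
    axon_na_vshift: float = -0.62

    def __post_init__(self):
        for name in PARAM_NAMES[:-1]:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES])

    @classmethod
    def from_vector(cls, x) -> "ChannelDensities":
        return cls(**{n: float(v) for n, v in zip(PARAM_NAMES, x)})

    def density(self, channel: str, region: int) -> float:
        suffix = ("dend", "soma", "axon")[region]
        return getattr(self, f"g_{channel}_{suffix}")


@dataclass(frozen=True)
class SynapseSpec:
    """Alpha-conductance synapse: g(t) = g_max ((t-t0)/τ) exp(1-(t-t0)/τ)."""

    site: object           # compartment index, landmark name, or (distance, branch)
    g_max: float           # nS
    onset_time: float      # ms
    tau: float = 0.4       # ms
    e_rev: float = 0.0     # mV

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.g_max < 0:
            raise ValueError("g_max must be non-negative")


@dataclass(frozen=True)
class StepStim:
    """Somatic (or arbitrary-site) current step, pA."""

    amplitude: float
    onset: float
    duration: float
    site: object = "soma"

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")


class CellModel:
    """Discretized cell: compartment geometry + channel conductances + landmarks."""

    def __init__(self, tree, densities, constants, max_seg_len=25.0,
                 ais_span=(0.0, 40.0), distal_axon_pos=300.0,
                 dend_gradients=None, stretched=False):
        self.tree = tree
        self.constants = constants
        self.max_seg_len = float(max_seg_len)
        self.ais_span = ais_span
        self.distal_axon_pos = distal_axon_pos
        self.dend_gradients = dict(dend_gradients or {})
        self.stretched = bool(stretched)
        self._build_geometry()
        self.set_densities(densities)

    # -- geometry -----------------------------------------------------------
    def _build_geometry(self):
        tree, rule = self.tree, self.max_seg_len
        if not np.any(tree.struct == AXON):
            # tolerated: axonal landmarks will simply be unavailable
            pass
        L = tree.edge_lengths()
        dist = tree.path_distance()
        radius = tree.radius

        lengths, diams, regions, parents, mids = [], [], [], [], []
        # soma: cylinder with length = diameter (area equals the equivalent sphere)
        d_soma = 2.0 * radius[tree.root]
        lengths.append(d_soma)
        diams.append(d_soma)
        regions.append(REGION_SOMA)
        parents.append(-1)
        mids.append(0.0)

        last_comp_of_node = {tree.root: 0}
        sections = tree.segments(DEND) + tree.segments(AXON)
        sections.sort(key=lambda seg: dist[seg[0]])
        for seg in sections:
            arc = np.concatenate([[0.0], np.cumsum([L[i] for i in seg[1:]])])
            sec_len = arc[-1]
            if sec_len <= 0:
                continue
            node_diam = 2.0 * radius[list(seg)]
            # origin node's radius belongs to the parent structure; use the
            # first in-section node's diameter at arc 0 for interpolation
            node_diam[0] = node_diam[1]
            n_comp = max(1, math.ceil(sec_len / rule))
            dx = sec_len / n_comp
            parent_comp = last_comp_of_node[seg[0]]
            region = _REGION_OF_STRUCT[tree.struct[seg[1]]]
            base_dist = dist[seg[0]]
            for k in range(n_comp):
                mid_arc = (k + 0.5) * dx
                d = float(np.interp(mid_arc, arc, node_diam))
                lengths.append(dx)
                diams.append(d)
                regions.append(region)
                parents.append(parent_comp)
                mids.append(base_dist + mid_arc)
                parent_comp = len(lengths) - 1
            last_comp_of_node[seg[-1]] = parent_comp

        self.length = np.asarray(lengths)
        self.diam = np.asarray(diams)
        self.region = np.asarray(regions, dtype=np.int64)
        self.parent = np.asarray(parents, dtype=np.int64)
        self.middist = np.asarray(mids)
        self.area = np.pi * self.diam * self.length          # µm²
        self.cap = 0.01 * self.constants.cm * self.area      # pF

        ra = self.constants.ra * 1e4                          # Ω·µm
        half_res = ra * (self.length / 2.0) / (np.pi * self.diam ** 2 / 4.0)
        gax = np.zeros(self.n_comp)
        for i in range(1, self.n_comp):
            gax[i] = 1e9 / (half_res[i] + half_res[self.parent[i]])  # nS
        self.gax = gax
        gax_sum = np.zeros(self.n_comp)
        for i in range(1, self.n_comp):
            gax_sum[i] += gax[i]
            gax_sum[self.parent[i]] += gax[i]
        self.gax_sum = gax_sum
        self._landmarks()

    def _landmarks(self):
        self.sites = {"soma": 0}
        axon = np.flatnonzero(self.region == REGION_AXON)
        if axon.size:
            mid = 0.5 * (self.ais_span[0] + self.ais_span[1])
            self.sites["AIS"] = int(axon[np.argmin(np.abs(self.middist[axon] - mid))])
            self.sites["distal_axon"] = int(
                axon[np.argmin(np.abs(self.middist[axon] - self.distal_axon_pos))])
        dend = np.flatnonzero(self.region == REGION_DEND)
        self._dend_comps = dend

    @property
    def n_comp(self) -> int:
        return self.length.size

    @property
    def max_dendrite_path(self) -> float:
        d = self._dend_comps
        if d.size == 0:
            return 0.0
        return float((self.middist[d] + self.length[d] / 2).max())

    # -- conductances -------------------------------------------------------
    def set_densities(self, densities: ChannelDensities):
        self.densities = densities
        a3 = self.area * 1e-3  # pS -> nS
        g = {}
        for chan in ("leak", "na", "k", "hcn"):
            dens = np.array([densities.density(chan, r) for r in self.region])
            g[chan] = dens * a3
        # optional distance-dependent dendritic scalings
        dend = self.region == REGION_DEND
        if dend.any():
            xmax = self.max_dendrite_path
            x = self.middist
            for chan, slope in self.dend_gradients.items():
                mult = 1.0 + slope * x / xmax
                g[chan] = np.where(dend, g[chan] * mult, g[chan])
            if self.stretched:
                w = np.ones(self.n_comp)
                xb = np.average(x[dend], weights=self.area[dend])
                w[dend] = x[dend] / xb  # area-weighted mean 1: total conductance kept
                for chan in g:
                    g[chan] = np.where(dend, g[chan] * w, g[chan])
        self.g_leak, self.g_na, self.g_k, self.g_hcn = (
            g["leak"], g["na"], g["k"], g["hcn"])
        self.na_row = (self.region == REGION_AXON).astype(np.int64)

    def with_densities(self, densities: ChannelDensities) -> "CellModel":
        """Cheap copy sharing geometry but with new channel densities."""
        new = object.__new__(CellModel)
        new.__dict__.update(self.__dict__)
        new.set_densities(densities)
        return new

    # -- site resolution ----------------------------------------------------
    def resolve_site(self, site) -> int:
        """Map a site spec to a compartment index.

        Accepts a compartment index, a landmark name ("soma", "AIS",
        "distal_axon"), or a ``(path_distance_µm, primary_dendrite)`` pair.
        """
        if isinstance(site, (int, np.integer)):
            if not 0 <= site < self.n_comp:
                raise ValueError(f"compartment index {site} out of range")
            return int(site)
        if isinstance(site, str):
            if site not in self.sites:
                raise ValueError(f"unknown recording site {site!r}; "
                                 f"available: {sorted(self.sites)}")
            return self.sites[site]
        if isinstance(site, tuple) and len(site) == 2:
            return self.locate_dendrite(float(site[0]), int(site[1]))
        raise TypeError(f"cannot interpret site spec {site!r}")

    def locate_dendrite(self, distance: float, branch: int = 0) -> int:
        """Compartment at dendritic path distance ``distance`` from the soma.

        The path descends primary dendrite ``branch`` taking the first child at
        every bifurcation.  ``distance`` 0 resolves to the soma compartment.
        """
        if distance <= 0:
            return 0
        children = [[] for _ in range(self.n_comp)]
        for i in range(1, self.n_comp):
            children[self.parent[i]].append(i)
        primaries = [c for c in children[0] if self.region[c] == REGION_DEND]
        if branch >= len(primaries):
            raise ValueError(f"dendrite branch {branch} does not exist")
        node = primaries[branch]
        while True:
            lo = self.middist[node] - self.length[node] / 2
            hi = self.middist[node] + self.length[node] / 2
            if distance <= hi + 1e-9:
                return node
            nxt = [c for c in children[node] if self.region[c] == REGION_DEND]
            if not nxt:
                raise ValueError(
                    f"distance {distance} µm beyond maximal path "
                    f"{hi:.1f} µm on this branch")
            node = nxt[0]

    def comps_at_distance(self, distance: float, max_n: int | None = None) -> list:
        """All dendritic compartments whose span contains ``distance`` (one per
        branch at that path distance from the soma)."""
        d = self._dend_comps
        lo = self.middist[d] - self.length[d] / 2
        hi = self.middist[d] + self.length[d] / 2
        sel = d[(lo <= distance) & (distance < hi)]
        out = [int(c) for c in sel]
        if max_n is not None:
            out = out[:max_n]
        if not out:
            raise ValueError(f"no dendritic cable at path distance {distance} µm "
                             f"(max {self.max_dendrite_path:.1f} µm)")
        return out

    def dendrite_position_at_cable_fraction(self, u: float) -> int:
        """Compartment at fraction ``u`` of total dendritic cable length.

        Used for uniform random synapse placement over the arbor.
        """
        d = self._dend_comps
        cum = np.cumsum(self.length[d])
        target = u * cum[-1]
        k = int(np.searchsorted(cum, target))
        return int(d[min(k, d.size - 1)])


def build_cell(tree: NeuronTree, densities: ChannelDensities,
               constants: BiophysConstants = BiophysConstants(),
               max_seg_len: float = 25.0, ais_span=(0.0, 40.0),
               distal_axon_pos: float = 300.0,
               dend_gradients=None, stretched: bool = False) -> CellModel:
    """Discretize ``tree`` into a simulatable :class:`CellModel`.

    ``dend_gradients`` maps channel names ("hcn", "leak", ...) to linear
    path-distance multiplier slopes ``g(x) = g0 (1 + s x / x_max)`` applied in
    the dendrites; ``stretched`` redistributes all dendritic conductance
    linearly toward the distal arbor at constant total conductance.
    """
    return CellModel(tree, densities, constants, max_seg_len=max_seg_len,
                     ais_span=ais_span, distal_axon_pos=distal_axon_pos,
                     dend_gradients=dend_gradients, stretched=stretched)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

_EMPTY_I = np.empty(0, dtype=np.int64)
_EMPTY_F = np.empty(0, dtype=float)


def _run_phase(cell, state, stims, syns, dt, nsteps, t_start, theta,
               rec_idx, rec_stride, stagger):
    v, m, h, n, q = state
    tabs = _ch.build_gate_tables(dt, cell.densities.axon_na_vshift)
    half = _ch.build_gate_tables(dt / 2.0, cell.densities.axon_na_vshift)
    n_out = nsteps // rec_stride + 1
    out = np.empty((rec_idx.size, n_out))
    out[:, 0] = v[rec_idx]
    if stims:
        s_comp = np.array([cell.resolve_site(s.site) for s in stims], dtype=np.int64)
        s_amp = np.array([s.amplitude for s in stims])
        s_on = np.array([s.onset for s in stims])
        s_dur = np.array([s.duration for s in stims])
    else:
        s_comp, s_amp, s_on, s_dur = _EMPTY_I, _EMPTY_F, _EMPTY_F, _EMPTY_F
    if syns:
        y_comp = np.array([cell.resolve_site(s.site) for s in syns], dtype=np.int64)
        y_g = np.array([s.g_max for s in syns])
        y_tau = np.array([s.tau for s in syns])
        y_on = np.array([s.onset_time for s in syns])
        y_e = np.array([s.e_rev for s in syns])
    else:
        y_comp, y_g, y_tau, y_on, y_e = _EMPTY_I, _EMPTY_F, _EMPTY_F, _EMPTY_F, _EMPTY_F

    status = integrate(
        v, m, h, n, q,
        cell.parent, cell.gax, cell.gax_sum, cell.cap,
        cell.g_leak, cell.g_na, cell.g_k, cell.g_hcn, cell.na_row,
        cell.constants.e_leak, cell.constants.e_na,
        cell.constants.e_k, cell.constants.e_hcn,
        tabs["m_inf"], tabs["m_exp"], tabs["h_inf"], tabs["h_exp"],
        tabs["n_inf"], tabs["n_exp"], tabs["q_inf"], tabs["q_exp"],
        half["m_exp"], half["h_exp"], half["n_exp"], half["q_exp"],
        tabs["v0"], tabs["dv_inv"],
        s_comp, s_amp, s_on, s_dur,
        y_comp, y_g, y_tau, y_on, y_e,
        dt, nsteps, t_start, theta,
        rec_idx, out, rec_stride, stagger)
    if status != STATUS_OK:
        raise FloatingPointError(
            "simulation diverged (non-finite membrane potential); "
            "check densities/dt")
    return out


def simulate(cell: CellModel, stims=(), synapses=(), record_sites=("soma",),
             dt: float = 0.025, t_stop: float = 100.0, v_init: float = -75.0,
             settle: float = 200.0, settle_dt: float = 0.1,
             theta: float = 0.5, rec_stride: int = 1) -> dict:
    """Integrate the model and return ``{site: Trace}`` voltage recordings.

    A stimulus-free settle period of ``settle`` ms (backward Euler at
    ``settle_dt``) removes initialization transients before the recorded phase;
    trace time 0 is the start of the recorded phase, so stimulus/synapse onsets
    are expressed on that axis.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > 0.05 and (cell.g_na.max() > 0 or cell.g_k.max() > 0):
        warnings.warn(f"dt = {dt} ms is coarse for active AP dynamics; "
                      "consider dt <= 0.025 ms", stacklevel=2)
    rec_idx = np.array([cell.resolve_site(s) for s in record_sites], dtype=np.int64)

    v = np.full(cell.n_comp, float(v_init))
    is_ax = cell.region == REGION_AXON
    m, h, n, q = _ch.steady_state_gates(v, cell.densities.axon_na_vshift, is_ax)
    state = (v, m, h, n, q)
    if settle > 0:
        n_settle = int(round(settle / settle_dt))
        _run_phase(cell, state, [], [], settle_dt, n_settle, -settle, 1.0,
                   np.array([0], dtype=np.int64), max(n_settle, 1), False)
    nsteps = int(round(t_stop / dt))
    out = _run_phase(cell, state, list(stims), list(synapses), dt, nsteps, 0.0,
                     theta, rec_idx, rec_stride, theta < 1.0)
    return {site: Trace(out[k], dt * rec_stride, t0=0.0, site=str(site), units="mV")
            for k, site in enumerate(record_sites)}


# ---------------------------------------------------------------------------
# Subthreshold EPSP metrics
# ---------------------------------------------------------------------------

def epsp_metrics(trace: Trace, stim_onset: float, baseline_window: float = 5.0,
                 noise_mult: float = 3.0, onset_peak_frac: float = 0.2):
    """Amplitude, 10-90% rise time, onset latency and decay τ of a subthreshold EPSP.

    Onset is the first time after ``stim_onset`` at which the signal exceeds
    baseline mean + ``noise_mult`` x baseline SD and subsequently reaches
    ``onset_peak_frac`` of the event peak.  Returns ``None`` when no deflection
    rises above the noise floor.
    """
    y, t = trace.y, trace.t
    i_on = trace.index_at(stim_onset)
    i_b0 = trace.index_at(stim_onset - baseline_window)
    base = y[i_b0:i_on + 1]
    if base.size < 2:
        raise ValueError("no pre-onset baseline available")
    b_mean, b_sd = float(np.mean(base)), float(np.std(base))

    seg = y[i_on:]
    i_pk = int(np.argmax(seg)) + i_on
    amp = float(y[i_pk] - b_mean)
    if amp <= max(5.0 * b_sd, 1e-9):
        return None

    thr = b_mean + max(noise_mult * b_sd, 1e-12)
    lvl20 = b_mean + onset_peak_frac * amp
    onset_t = None
    i = i_on
    while i < i_pk:
        if y[i] > thr:
            # require the 20%-of-peak level to be reached before re-crossing
            j = i
            ok = False
            while j <= i_pk:
                if y[j] >= lvl20:
                    ok = True
                    break
                if y[j] <= thr:
                    break
                j += 1
            if ok:
                onset_t = _cross_time(t, y, i - 1, thr) if i > i_on else t[i]
                break
            i = j
        i += 1
    if onset_t is None:
        onset_t = t[i_pk]

    l10 = b_mean + 0.1 * amp
    l90 = b_mean + 0.9 * amp
    t10 = _first_cross(t, y, i_on, i_pk, l10)
    t90 = _first_cross(t, y, i_on, i_pk, l90)
    rise = t90 - t10

    decay_tau = _fit_decay_tau(t, y, i_pk, b_mean, amp)
    return {
        "amplitude": amp,
        "rise_time_10_90": rise,
        "onset_latency": float(onset_t - stim_onset),
        "decay_tau": decay_tau,
    }


def _cross_time(t, y, i, level):
    """Linear-interpolated upward crossing time of ``level`` between i and i+1."""
    if y[i + 1] == y[i]:
        return t[i + 1]
    f = (level - y[i]) / (y[i + 1] - y[i])
    f = min(max(f, 0.0), 1.0)
    return t[i] + f * (t[i + 1] - t[i])


def _first_cross(t, y, i0, i1, level):
    for i in range(i0, i1):
        if y[i] <= level <= y[i + 1]:
            return _cross_time(t, y, i, level)
    return t[i1]


def _fit_decay_tau(t, y, i_pk, baseline, amp, hi=0.9, lo=0.2):
    """Decay time constant by log-linear fit between hi and lo of the amplitude."""
    rel = y[i_pk:] - baseline
    below_hi = np.flatnonzero(rel <= hi * amp)
    below_lo = np.flatnonzero(rel <= lo * amp)
    if below_hi.size == 0:
        return float("nan")
    j0 = below_hi[0]
    j1 = below_lo[0] if below_lo.size else rel.size - 1
    if j1 - j0 < 3:
        j1 = min(j0 + 3, rel.size - 1)
    seg = rel[j0:j1 + 1]
    tt = t[i_pk + j0:i_pk + j1 + 1]
    good = seg > 0
    if good.sum() < 3:
        return float("nan")
    slope, _ = np.polyfit(tt[good], np.log(seg[good]), 1)
    return float(-1.0 / slope) if slope < 0 else float("nan")
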