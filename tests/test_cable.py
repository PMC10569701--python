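"""Cable-model discretization and integrator physics.

The solver is checked against closed forms: RC charging of an isopotential
compartment, the sealed-end analytic input resistance of passive cables,
exact charge conservation with all channels blocked, passive reciprocity of
transfer responses, the alpha-synapse conductance time course, and time-step
convergence of AP timing.
"""

import math

import numpy as np
import pytest

from fsin.cable import (BiophysConstants, ChannelDensities, StepStim,
                        SynapseSpec, build_cell, epsp_metrics, simulate)
from fsin.fitting import first_spike_time
from fsin.morphology import DEND, SOMA, MorphoParams, NeuronTree, generate_morphology
from fsin.presets import FITTED_DENSITIES
from fsin.traceio import Trace

PASSIVE = ChannelDensities(1.0, 1.0, 1.0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0.0)


def soma_only_tree(radius=10.0):
    return NeuronTree([SOMA], [(0, 0, 0)], [radius], [-1])


def cable_tree(diam, length, step=5.0):
    n = int(length / step)
    struct = [SOMA] + [DEND] * n
    xyz = [(0, 0, 0)] + [(step * (k + 1), 0, 0) for k in range(n)]
    return NeuronTree(struct, xyz, [diam / 2] * (n + 1), [-1] + list(range(n)))


def analytic_sealed_rin(d_um, L_um, gl_ps_um2, Ra=100.0):
    """Input resistance (MΩ) of a sealed-end cylinder, R∞ coth(L/λ)."""
    Rm = 1.0 / (gl_ps_um2 * 1e-4)          # Ω·cm²
    a = d_um * 1e-4 / 2                    # cm
    rm = Rm / (2 * math.pi * a)            # Ω·cm
    ra = Ra / (math.pi * a * a)            # Ω/cm
    lam = math.sqrt(rm / ra)
    return math.sqrt(rm * ra) / math.tanh(L_um * 1e-4 / lam) * 1e-6


class TestBuild:
    def test_single_cylinder_compartment_count(self):
        cell = build_cell(cable_tree(2.0, 100.0), PASSIVE, max_seg_len=10.0)
        assert (cell.region == 0).sum() == 10  # 100 µm / 10 µm rule

    def test_compartment_count_matches_ceil_rule(self, human_tree):
        rule = 25.0
        cell = build_cell(human_tree, PASSIVE, max_seg_len=rule)
        L = human_tree.edge_lengths()
        expected = 0
        for seg in human_tree.segments(DEND) + human_tree.segments(2):
            expected += math.ceil(sum(L[i] for i in seg[1:]) / rule - 1e-9)
        assert cell.n_comp == expected + 1  # + soma

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError, match="g_na_soma"):
            ChannelDensities(1, 1, 1, 0, -5.0, 0, 0, 0, 0, 0, 0, 0, 0.0)

    def test_landmarks_exist(self, fitted_cell):
        assert fitted_cell.sites["soma"] == 0
        ais = fitted_cell.sites["AIS"]
        assert fitted_cell.region[ais] == 2
        assert abs(fitted_cell.middist[ais] - 20.0) < 15.0
        assert abs(fitted_cell.middist[fitted_cell.sites["distal_axon"]] - 300.0) < 15.0

    def test_unknown_site_error_names_available(self, fitted_cell):
        with pytest.raises(ValueError, match="AIS"):
            fitted_cell.resolve_site("axon_hillock")


class TestPassivePhysics:
    def test_rc_step_response(self):
        """Isopotential compartment: deflection I·R, charging τ = C/g."""
        cell = build_cell(soma_only_tree(), PASSIVE)
        tr = simulate(cell, stims=[StepStim(100.0, 10.0, 100.0)], dt=0.025,
                      t_stop=110.0, settle=50.0)["soma"]
        R = 1.0 / cell.g_leak[0]  # GΩ
        defl = tr.y[tr.index_at(109.5)] - tr.y[tr.index_at(9.5)]
        assert defl == pytest.approx(100.0 * R, rel=1e-3)
        tau = cell.cap[0] / cell.g_leak[0]
        i0 = tr.index_at(10.0)
        rel = (tr.y[tr.index_at(109.5)] - tr.y) / (tr.y[tr.index_at(109.5)] - tr.y[i0])
        t_tau = tr.t[i0 + np.flatnonzero(rel[i0:] < math.exp(-1))[0]] - 10.0
        assert t_tau == pytest.approx(tau, rel=0.02)

    def test_rest_is_leak_reversal(self):
        cell = build_cell(soma_only_tree(), PASSIVE)
        tr = simulate(cell, dt=0.025, t_stop=50.0)["soma"]
        assert np.allclose(tr.y, -75.0, atol=1e-6)

    @pytest.mark.parametrize("d,L,gl", [(2.0, 500.0, 0.5), (1.0, 300.0, 1.0),
                                        (4.0, 1000.0, 0.2)])
    def test_cable_input_resistance_analytic(self, d, L, gl):
        """Sealed-end cable R_in matches the coth closed form within 1%."""
        dens = ChannelDensities(gl, gl, gl, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0.0)
        cell = build_cell(cable_tree(d, L), dens, max_seg_len=5.0)
        tr = simulate(cell, stims=[StepStim(-100.0, 10.0, 600.0)], dt=0.1,
                      t_stop=610.0, settle=100.0, settle_dt=0.5)["soma"]
        rin_sim = (tr.y[tr.index_at(9.5)] - tr.y[tr.index_at(609.0)]) / 100.0 * 1e3
        # soma cylinder (L = diam) in parallel with the cable
        r_cable = analytic_sealed_rin(d, L, gl)
        g_soma_uS = gl * 1e-6 * math.pi * (2 * cell.diam[0] / 2) ** 2
        rin_expect = 1.0 / (1.0 / r_cable + g_soma_uS)
        assert rin_sim == pytest.approx(rin_expect, rel=0.01)

    def test_charge_conservation_when_blocked(self, human_tree):
        """With all conductances zero, injected charge equals Σ C ΔV exactly."""
        dens = ChannelDensities(0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0.0)
        cell = build_cell(human_tree, dens)
        amp, dur = 50.0, 40.0
        tr = simulate(cell, stims=[StepStim(amp, 5.0, dur)],
                      record_sites=list(range(cell.n_comp)), dt=0.025,
                      t_stop=60.0, settle=0.0)
        dv = np.array([tr[i].y[-1] - tr[i].y[0] for i in range(cell.n_comp)])
        q_stored = float((cell.cap * dv).sum())          # pF·mV = pA·ms = fC
        assert q_stored == pytest.approx(amp * dur, rel=1e-6)

    def test_passive_reciprocity(self, mouse_tree):
        """Steady-state transfer soma→site equals site→soma."""
        cell = build_cell(mouse_tree, PASSIVE)
        site = cell.locate_dendrite(100.0, 0)
        tr1 = simulate(cell, stims=[StepStim(-50.0, 10.0, 400.0, site="soma")],
                       record_sites=(site,), dt=0.1, t_stop=410.0,
                       settle_dt=0.5)[site]
        tr2 = simulate(cell, stims=[StepStim(-50.0, 10.0, 400.0, site=site)],
                       record_sites=("soma",), dt=0.1, t_stop=410.0,
                       settle_dt=0.5)["soma"]
        d1 = tr1.y[tr1.index_at(409.0)] - tr1.y[tr1.index_at(9.0)]
        d2 = tr2.y[tr2.index_at(409.0)] - tr2.y[tr2.index_at(9.0)]
        assert d1 == pytest.approx(d2, rel=1e-6)


class TestSynapse:
    def test_alpha_conductance_time_course(self):
        """dV/dt of a near-clamped passive compartment tracks the alpha form:
        peak at t0+τ, and 2 e⁻¹ of peak at t0+2τ."""
        # huge capacitance keeps V ≈ const so dV/dt ∝ g(t)(E_rev − V)
        const = BiophysConstants(cm=900.0)
        cell = build_cell(soma_only_tree(), PASSIVE, constants=const)
        tau = 0.4
        tr = simulate(cell, synapses=[SynapseSpec(0, 2.0, 5.0, tau=tau)],
                      dt=0.002, t_stop=10.0, settle=10.0)["soma"]
        dvdt = np.gradient(tr.y, tr.dt)
        i_pk = int(np.argmax(dvdt))
        assert tr.t[i_pk] == pytest.approx(5.0 + tau, abs=0.01)
        at_2tau = dvdt[tr.index_at(5.0 + 2 * tau)]
        assert at_2tau / dvdt[i_pk] == pytest.approx(2 * math.exp(-1), rel=0.01)

    def test_invalid_synapse_params(self):
        with pytest.raises(ValueError):
            SynapseSpec(0, 1.0, 0.0, tau=-0.1)
        with pytest.raises(ValueError):
            SynapseSpec(0, -1.0, 0.0)


class TestActiveDynamics:
    def test_fs_firing_with_fitted_densities(self, fitted_cell):
        """A 200 pA/100 ms step elicits repetitive brief APs."""
        tr = simulate(fitted_cell, stims=[StepStim(200.0, 10.0, 100.0)],
                      dt=0.005, t_stop=112.0)["soma"]
        from fsin.ephys import ap_waveform_features, detect_aps
        peaks = detect_aps(tr)
        assert peaks.size >= 5
        apf = ap_waveform_features(tr, peaks[0], target_dt=tr.dt)
        assert apf.half_width < 0.6

    def test_dt_convergence_of_ap_timing(self, fitted_cell):
        """Halving dt from 2 µs moves the AP peak by < 1 µs and < 0.1 mV."""
        res = {}
        for dt in (0.002, 0.001):
            tr = simulate(fitted_cell, stims=[StepStim(800.0, 2.0, 4.0)],
                          dt=dt, t_stop=10.0)["soma"]
            t_pk = first_spike_time(tr, 0.0)
            res[dt] = (t_pk, tr.y.max())
        assert abs(res[0.002][0] - res[0.001][0]) < 1e-3   # ms
        assert abs(res[0.002][1] - res[0.001][1]) < 0.1    # mV

    def test_divergence_raises(self):
        cell = build_cell(soma_only_tree(), PASSIVE)
        with pytest.raises(ValueError):
            simulate(cell, dt=-1.0, t_stop=10.0)


class TestEPSPMetrics:
    def make_alpha_epsp(self, amp=1.0, tau=2.0, onset=20.0, dt=0.025,
                        baseline=-70.0, decay_tau=None):
        t = np.arange(0.0, 120.0, dt)
        y = np.full(t.size, baseline)
        x = (t - onset) / tau
        rise = x > 0
        y[rise] += amp * x[rise] * np.exp(1.0 - x[rise])
        return Trace(y, dt, units="mV")

    def test_amplitude_recovery(self):
        tr = self.make_alpha_epsp(amp=1.0)
        met = epsp_metrics(tr, 20.0)
        assert met["amplitude"] == pytest.approx(1.0, abs=1e-3)
        assert met["onset_latency"] == pytest.approx(0.0, abs=0.05)

    def test_decay_tau_recovery(self):
        """A pure exponential decay after the peak is recovered (τ = 17.6 ms)."""
        dt, tau = 0.025, 17.6
        t = np.arange(0.0, 200.0, dt)
        y = np.full(t.size, -70.0)
        rise = (t >= 20.0) & (t < 22.0)
        y[rise] = -70.0 + 2.0 * (t[rise] - 20.0) / 2.0
        decay = t >= 22.0
        y[decay] = -70.0 + 2.0 * np.exp(-(t[decay] - 22.0) / tau)
        met = epsp_metrics(Trace(y, dt, units="mV"), 20.0)
        assert met["decay_tau"] == pytest.approx(tau, rel=0.01)

    def test_flat_trace_is_no_event(self):
        tr = Trace(np.full(4000, -70.0), 0.025, units="mV")
        assert epsp_metrics(tr, 20.0) is None
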