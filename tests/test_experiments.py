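"""In-silico experiments: dendritic filtering, boost mechanisms, AP timing,
dendritic scaling, disynaptic-delay composition."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from fsin.cable import (BiophysConstants, ChannelDensities, StepStim,
                        build_cell, epsp_metrics, simulate)
from fsin.experiments import (CellSpec, ap_delay_scan, apply_boost_mechanism,
                              compose_disynaptic_delay,
                              dendritic_scaling_experiment, epsp_distance_scan,
                              random_synapse_experiment)
from fsin.morphology import SOMA, NeuronTree
from fsin.presets import FITTED_DENSITIES

# distances chosen to land in distinct compartments on both species' trees
DISTANCES = [10.0, 38.0, 63.0, 87.0, 111.0]
G_SUB = 1.0    # nS, subthreshold single synapse
G_SUPRA = 3.0   # nS per synapse in the 20-synapse delay-scan cohorts


@pytest.fixture(scope="module")
def human_spec(human_tree):
    return CellSpec(human_tree, FITTED_DENSITIES)


@pytest.fixture(scope="module")
def mouse_spec(mouse_tree):
    return CellSpec(mouse_tree, FITTED_DENSITIES)


@pytest.fixture(scope="module")
def human_scan(human_spec):
    return epsp_distance_scan(human_spec, DISTANCES, g_syn=G_SUB).records


@pytest.fixture(scope="module")
def mouse_scan(mouse_spec):
    return epsp_distance_scan(mouse_spec, DISTANCES, g_syn=G_SUB).records


class TestEPSPDistanceScan:
    def test_amplitude_decreases_rise_time_increases(self, human_scan, mouse_scan):
        for rec in (human_scan, mouse_scan):
            amp = rec.amplitude.to_numpy()
            rise = rec.rise_time.to_numpy()
            assert np.all(np.diff(amp) < 0)
            assert np.all(np.diff(rise) > 0)

    def test_human_amplitude_below_mouse_at_matched_distance(self, human_scan,
                                                             mouse_scan):
        assert np.all(human_scan.amplitude.to_numpy()
                      < mouse_scan.amplitude.to_numpy())

    def test_somatic_synapse_matches_isopotential_oracle(self):
        """On a soma-only cell, the distance-0 scan equals an independent ODE
        integration of the single-compartment RC + alpha-conductance model."""
        dens = ChannelDensities(1.0, 1.0, 1.0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0.0)
        tree = NeuronTree([SOMA], [(0, 0, 0)], [10.0], [-1])
        cell = build_cell(tree, dens)
        res = epsp_distance_scan(cell, [0.0], g_syn=0.5, dt=0.005).records
        g_l, c, tau, e_rev, e_l = cell.g_leak[0], cell.cap[0], 0.4, 0.0, -75.0

        def rhs(t, v):
            x = (t - 5.0) / tau
            g = 0.5 * x * np.exp(1 - x) if x > 0 else 0.0
            return (g_l * (e_l - v) + g * (e_rev - v)) / c

        sol = solve_ivp(rhs, (0.0, 60.0), [e_l], max_step=0.005, rtol=1e-9,
                        atol=1e-9, dense_output=True)
        oracle_amp = sol.y[0].max() - e_l
        assert res.amplitude[0] == pytest.approx(oracle_amp, rel=1e-3)

    def test_distance_beyond_tree_names_maximum(self, mouse_spec):
        with pytest.raises(ValueError, match="maximal path"):
            epsp_distance_scan(mouse_spec, [5000.0], g_syn=G_SUB)


class TestBoostMechanisms:
    def test_synapse_x2_amplitudes_dominate(self, human_spec, human_scan):
        boosted = apply_boost_mechanism(human_spec, "synapse_x2")
        rec = epsp_distance_scan(boosted, DISTANCES, g_syn=G_SUB).records
        assert np.all(rec.amplitude.to_numpy() > human_scan.amplitude.to_numpy())

    def test_synapse_x2_rescues_into_mouse_range(self, human_spec, mouse_scan):
        """Doubled synaptic strength brings the human somatic amplitudes into
        the mouse model's amplitude range over the matched-distance scan."""
        boosted = apply_boost_mechanism(human_spec, "synapse_x2")
        rec = epsp_distance_scan(boosted, DISTANCES, g_syn=G_SUB).records
        m_lo, m_hi = mouse_scan.amplitude.min(), mouse_scan.amplitude.max()
        assert np.all(rec.amplitude.to_numpy() >= 0.95 * m_lo)
        assert np.all(rec.amplitude.to_numpy() <= 1.05 * m_hi)

    def test_zero_slope_gradient_is_identity(self, human_spec):
        flat = apply_boost_mechanism(human_spec, "ih_gradient", gradient_slope=0.0)
        c0, c1 = human_spec.build(), flat.build()
        assert np.allclose(c0.g_hcn, c1.g_hcn)
        assert np.allclose(c0.g_leak, c1.g_leak)

    def test_gradients_and_stretch_preserve_or_shift_conductance(self, human_spec):
        c0 = human_spec.build()
        grad = apply_boost_mechanism(human_spec, "ih_gradient").build()
        dend = c0.region == 0
        assert np.all(grad.g_hcn[dend] >= c0.g_hcn[dend])
        stretched = apply_boost_mechanism(human_spec, "stretched_conductance").build()
        # conductance-preserving redistribution: totals match, distal up-weighted
        for g0, g1 in ((c0.g_leak, stretched.g_leak), (c0.g_hcn, stretched.g_hcn)):
            assert g1[dend].sum() == pytest.approx(g0[dend].sum(), rel=1e-6)
        distal = dend & (c0.middist > np.median(c0.middist[dend]))
        assert stretched.g_leak[distal].sum() > c0.g_leak[distal].sum()

    def test_unknown_mechanism_rejected(self, human_spec):
        with pytest.raises(ValueError, match="unknown boost"):
            apply_boost_mechanism(human_spec, "magic")


class TestAPDelayScan:
    @pytest.fixture(scope="class")
    def delays(self, human_spec, mouse_spec):
        out = {}
        out["human"] = ap_delay_scan(human_spec, n_sites=6, g_syn=G_SUPRA).records
        out["human_x2"] = ap_delay_scan(
            apply_boost_mechanism(human_spec, "synapse_x2"), n_sites=6,
            g_syn=G_SUPRA).records
        out["mouse"] = ap_delay_scan(mouse_spec, n_sites=6, g_syn=G_SUPRA).records
        return out

    def test_delay_increases_with_distance(self, delays):
        for rec in delays.values():
            ok = rec[rec.spiked]
            assert len(ok) >= 4
            assert ok.ap_delay.is_monotonic_increasing

    def test_doubled_synapse_shortens_delays_site_by_site(self, delays):
        h, hx2 = delays["human"], delays["human_x2"]
        both = h.spiked & hx2.spiked
        assert np.all(hx2.ap_delay[both].to_numpy() < h.ap_delay[both].to_numpy())

    def test_same_seed_reproducible(self, human_spec):
        a = ap_delay_scan(human_spec, n_sites=4, g_syn=G_SUPRA,
                          random_sites=True, seed=5).records
        b = ap_delay_scan(human_spec, n_sites=4, g_syn=G_SUPRA,
                          random_sites=True, seed=5).records
        assert a.equals(b)


class TestRandomSynapses:
    def test_same_seed_identical_configurations(self, human_spec):
        a = random_synapse_experiment(human_spec, n_configs=2, n_syn=4,
                                      g_syn=G_SUB, seed=3).records
        b = random_synapse_experiment(human_spec, n_configs=2, n_syn=4,
                                      g_syn=G_SUB, seed=3).records
        assert a.equals(b)

    def test_single_synapse_consistent_with_distance_scan(self, human_spec):
        cell = human_spec.build()
        rec = random_synapse_experiment(cell, n_configs=1, n_syn=1,
                                        g_syn=G_SUB, seed=11).records
        rng = np.random.default_rng(11)
        comp = cell.dendrite_position_at_cable_fraction(rng.random(1)[0])
        from fsin.cable import SynapseSpec
        tr = simulate(cell, synapses=[SynapseSpec(comp, G_SUB, 5.0)],
                      record_sites=("soma",), dt=0.025, t_stop=60.0)["soma"]
        met = epsp_metrics(tr, 5.0)
        assert rec.amplitude[0] == pytest.approx(met["amplitude"], rel=1e-9)

    def test_human_median_amplitude_below_mouse(self, human_spec, mouse_spec):
        h = random_synapse_experiment(human_spec, n_configs=6, n_syn=5,
                                      g_syn=G_SUB, seed=1).records
        m = random_synapse_experiment(mouse_spec, n_configs=6, n_syn=5,
                                      g_syn=G_SUB, seed=1).records
        assert h.amplitude.median() < m.amplitude.median()


class TestDendriticScaling:
    @pytest.fixture(scope="class")
    def scaling(self, human_tree):
        return dendritic_scaling_experiment(human_tree, FITTED_DENSITIES,
                                            scales=(0.5, 1.0, 1.5)).records

    def test_onset_rapidity_increases_with_scale(self, scaling):
        rap = scaling.onset_rapidity.to_numpy()
        assert rap[2] > rap[1] > rap[0]

    def test_ais_leads_soma_at_all_scales(self, scaling):
        assert np.all(scaling.ais_soma_lead.to_numpy() > 0)

    def test_ais_lead_increases_with_scale(self, scaling):
        lead = scaling.ais_soma_lead.to_numpy()
        assert lead[2] > lead[1] > lead[0]


class TestDisynapticDelay:
    def test_human_stage_delays_compose(self):
        assert compose_disynaptic_delay([1.31, 0.85, 0.6, 0.75]) == pytest.approx(3.51)

    def test_mouse_stage_delays_compose(self):
        assert compose_disynaptic_delay([1.14, 0.85, 0.4, 1.06]) == pytest.approx(3.45)

    def test_empty_composes_to_zero(self):
        assert compose_disynaptic_delay([]) == 0.0

    def test_negative_stage_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            compose_disynaptic_delay([1.0, -0.1])

    def test_order_invariance(self):
        stages = [1.31, 0.85, 0.6, 0.75]
        assert compose_disynaptic_delay(stages) == pytest.approx(
            compose_disynaptic_delay(stages[::-1]))
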