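"""Fast-spiking channel gating kinetics.

The conductance set comprises a transient Na+ current (m^3 h), a fast
delayed-rectifier K+ current (n^4), a slow single-gate HCN current and ohmic
leak.  Rate functions follow the classic fast-spiking interneuron formulation
of Wang & Buzsaki (hippocampal basket-cell model), with the temperature-like
speedup factor applied to the slow gates and the rates calibrated against
the 34 degC feature objectives used for model fitting.  The axonal Na+
voltage dependence can be left-shifted by a free parameter to mimic
low-threshold Nav1.6 channels concentrated in the axon.

All voltages in mV, times in ms, rates in 1/ms.
"""

from __future__ import annotations

import numpy as np

# speedup of h and n gate kinetics (the original formulation's phi)
PHI = 5.0
# speedup of the m gate: the classic Wang-Buzsaki formulation treats
# activation as instantaneous; a finite but fast tau_m (~0.05-0.1 ms)
# preserves regenerative spike initiation while keeping m as an ODE
PHI_M = 5.0
# lower bound keeps table-driven Rush-Larsen updates well-conditioned
TAU_FLOOR = 5e-3


def _vtrap(x, y):
    """x / (1 - exp(-x/y)) with the removable singularity at x = 0 handled."""
    x = np.asarray(x, dtype=float)
    out = np.where(np.abs(x / y) < 1e-6, y * (1.0 + x / (2.0 * y)), x / (1.0 - np.exp(-x / y)))
    return out


def na_m_inf_tau(v):
    a = PHI_M * 0.1 * _vtrap(v + 35.0, 10.0)
    b = PHI_M * 4.0 * np.exp(-(v + 60.0) / 18.0)
    tau = 1.0 / (a + b)
    return a * tau, np.maximum(tau, TAU_FLOOR)


def na_h_inf_tau(v):
    a = PHI * 0.07 * np.exp(-(v + 58.0) / 20.0)
    b = PHI * 1.0 / (1.0 + np.exp(-(v + 28.0) / 10.0))
    tau = 1.0 / (a + b)
    return a * tau, np.maximum(tau, TAU_FLOOR)


def kdr_n_inf_tau(v):
    a = PHI * 0.01 * _vtrap(v + 34.0, 10.0)
    b = PHI * 0.125 * np.exp(-(v + 44.0) / 80.0)
    tau = 1.0 / (a + b)
    return a * tau, np.maximum(tau, TAU_FLOOR)


def hcn_q_inf_tau(v):
    inf = 1.0 / (1.0 + np.exp((v + 82.0) / 7.0))
    tau = np.full_like(np.asarray(v, dtype=float), 40.0)
    return inf, tau


# ---------------------------------------------------------------------------
# Voltage-indexed gating tables for the integrator
# ---------------------------------------------------------------------------

V_MIN, V_MAX, DV = -130.0, 80.0, 0.05


def build_gate_tables(dt: float, axon_na_vshift: float):
    """Precompute x_inf and exp(-dt/tau_x) on a voltage grid.

    Na+ tables have two rows: row 0 for somatodendritic compartments, row 1
    with the axonal voltage shift applied (gating evaluated at v - shift).
    Returns a dict of float64 arrays plus the grid origin/spacing.
    """
    v = np.arange(V_MIN, V_MAX + DV / 2, DV)
    tabs = {}
    for name, fn, shifted in (
        ("m", na_m_inf_tau, True),
        ("h", na_h_inf_tau, True),
        ("n", kdr_n_inf_tau, False),
        ("q", hcn_q_inf_tau, False),
    ):
        rows_inf, rows_exp = [], []
        shifts = (0.0, axon_na_vshift) if shifted else (0.0,)
        for s in shifts:
            inf, tau = fn(v - s)
            rows_inf.append(inf)
            rows_exp.append(np.exp(-dt / tau))
        tabs[f"{name}_inf"] = np.ascontiguousarray(rows_inf)
        tabs[f"{name}_exp"] = np.ascontiguousarray(rows_exp)
    tabs["v0"] = V_MIN
    tabs["dv_inv"] = 1.0 / DV
    return tabs


def steady_state_gates(v, axon_na_vshift, is_axon):
    """Gate values at their voltage-clamped steady state (for initialization)."""
    v = np.asarray(v, dtype=float)
    shift = np.where(is_axon, axon_na_vshift, 0.0)
    m, _ = na_m_inf_tau(v - shift)
    h, _ = na_h_inf_tau(v - shift)
    n, _ = kdr_n_inf_tau(v)
    q, _ = hcn_q_inf_tau(v)
    return m, h, n, q
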