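"""Numba-jitted integrator for the branched-cable Hodgkin-Huxley model.

The spatial discretization is a tree of cylindrical compartments; at each time
step a tridiagonal-on-tree linear system is solved directly in Hines order
(children eliminated into parents, then back-substitution).  Voltage is
advanced with a theta-method (theta = 0.5 Crank-Nicolson by default, theta = 1
backward Euler); gating variables are advanced with exact exponential
(Rush-Larsen) updates from voltage-indexed lookup tables, staggered by half a
time step relative to voltage so that the Crank-Nicolson scheme retains
second-order accuracy.

Units: mV, ms, pA, nS, pF.
"""

import numba
import numpy as np

STATUS_OK = 0
STATUS_NONFINITE = 1


@numba.njit(cache=True, fastmath=True)
def _lookup(tab, row, xf, j):
    w = xf - j
    return tab[row, j] * (1.0 - w) + tab[row, j + 1] * w


@numba.njit(cache=True, fastmath=True)
def integrate(v, m, h, n, q,
              parent, gax, gax_sum, cap,
              gl, gna, gk, gh, na_row,
              el, ena, ek, ehcn,
              m_inf, m_exp, h_inf, h_exp,
              n_inf, n_exp, q_inf, q_exp,
              m_exp_half, h_exp_half, n_exp_half, q_exp_half,
              v0, dv_inv,
              stim_comp, stim_amp, stim_on, stim_dur,
              syn_comp, syn_gmax, syn_tau, syn_on, syn_erev,
              dt, nsteps, t_start, theta,
              rec_idx, out, rec_stride, stagger):
    ncomp = v.size
    nv = m_inf.shape[1]
    diag = np.empty(ncomp)
    rhs = np.empty(ncomp)
    G = np.empty(ncomp)
    gE = np.empty(ncomp)
    cdt = cap / dt

    for k in range(nsteps):
        t_mid = t_start + (k + 0.5) * dt

        # --- gate update (Rush-Larsen); first step advances dt/2 if staggered
        half = stagger and k == 0
        for i in range(ncomp):
            xf = (v[i] - v0) * dv_inv
            if xf < 0.0:
                xf = 0.0
            elif xf > nv - 1.001:
                xf = nv - 1.001
            j = int(xf)
            r = na_row[i]
            mi = _lookup(m_inf, r, xf, j)
            hi = _lookup(h_inf, r, xf, j)
            ni = _lookup(n_inf, 0, xf, j)
            qi = _lookup(q_inf, 0, xf, j)
            if half:
                em = _lookup(m_exp_half, r, xf, j)
                eh = _lookup(h_exp_half, r, xf, j)
                en = _lookup(n_exp_half, 0, xf, j)
                eq = _lookup(q_exp_half, 0, xf, j)
            else:
                em = _lookup(m_exp, r, xf, j)
                eh = _lookup(h_exp, r, xf, j)
                en = _lookup(n_exp, 0, xf, j)
                eq = _lookup(q_exp, 0, xf, j)
            m[i] = mi + (m[i] - mi) * em
            h[i] = hi + (h[i] - hi) * eh
            n[i] = ni + (n[i] - ni) * en
            q[i] = qi + (q[i] - qi) * eq

            m3h = m[i] * m[i] * m[i] * h[i]
            n4 = n[i] * n[i]
            n4 *= n4
            gna_i = gna[i] * m3h
            gk_i = gk[i] * n4
            gh_i = gh[i] * q[i]
            G[i] = gl[i] + gna_i + gk_i + gh_i
            gE[i] = gl[i] * el + gna_i * ena + gk_i * ek + gh_i * ehcn

        # --- synapses (alpha conductance) evaluated at the step midpoint
        for s in range(syn_comp.size):
            x = (t_mid - syn_on[s]) / syn_tau[s]
            if x <= 0.0 or x > 60.0:
                continue
            g = syn_gmax[s] * x * np.exp(1.0 - x)
            c = syn_comp[s]
            G[c] += g
            gE[c] += g * syn_erev[s]

        # --- assemble theta-method system
        for i in range(ncomp):
            diag[i] = cdt[i] + theta * (G[i] + gax_sum[i])
            rhs[i] = cdt[i] * v[i] + gE[i] + (1.0 - theta) * (-G[i] * v[i])
        if theta < 1.0:
            w = 1.0 - theta
            for i in range(1, ncomp):
                p = parent[i]
                f = gax[i] * (v[p] - v[i]) * w
                rhs[i] += f
                rhs[p] -= f

        # --- current steps
        for s in range(stim_comp.size):
            if stim_on[s] <= t_mid < stim_on[s] + stim_dur[s]:
                rhs[stim_comp[s]] += stim_amp[s]

        # --- Hines solve (parent[i] < i guaranteed by ordering)
        for i in range(ncomp - 1, 0, -1):
            p = parent[i]
            f = (-theta * gax[i]) / diag[i]
            diag[p] -= f * (-theta * gax[i])
            rhs[p] -= f * rhs[i]
        v[0] = rhs[0] / diag[0]
        for i in range(1, ncomp):
            v[i] = (rhs[i] + theta * gax[i] * v[parent[i]]) / diag[i]

        if (k + 1) % rec_stride == 0:
            col = (k + 1) // rec_stride
            for r in range(rec_idx.size):
                out[r, col] = v[rec_idx[r]]
        if k % 256 == 0 and not np.isfinite(v[0]):
            return STATUS_NONFINITE

    if not np.isfinite(v[0]):
        return STATUS_NONFINITE
    return STATUS_OK
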