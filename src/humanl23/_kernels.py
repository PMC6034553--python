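"""Numba kernels: backward-Euler integration with Hines tree elimination.

The compartment arrays are ordered parents-before-children, so one
leaf-to-root elimination sweep and one root-to-leaf back-substitution solve
the implicit step exactly.  Synaptic conductances are evaluated at the end
of the step; the NMDA magnesium-block factor uses the previous step's
voltage (semi-implicit), which keeps the per-step system linear.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# gate kinds
_GATE_OFF = 0
_GATE_V = 1
_GATE_CA = 2


@njit(cache=True)
def _static_diag(parent, g_ax, cm, g_pas, dt):
    n = parent.size
    d0 = np.empty(n)
    for i in range(n):
        d0[i] = cm[i] / dt + g_pas[i] + g_ax[i]
    for i in range(1, n):
        d0[parent[i]] += g_ax[i]
    return d0


@njit(cache=True, inline="always")
def _hines_solve(parent, g_ax, d, rhs, v):
    n = parent.size
    for i in range(n - 1, 0, -1):
        p = parent[i]
        f = g_ax[i] / d[i]
        d[p] -= f * g_ax[i]
        rhs[p] += f * rhs[i]
    v[0] = rhs[0] / d[0]
    for i in range(1, n):
        v[i] = (rhs[i] + g_ax[i] * v[parent[i]]) / d[i]


@njit(cache=True, inline="always")
def _add_stimuli(t_next, d, rhs, v,
                 stim_comp, stim_amp, stim_t0, stim_t1,
                 syn_comp, syn_g, syn_taur, syn_taud, syn_on, syn_e,
                 syn_vdep, syn_gamma, syn_nmg):
    for s in range(stim_comp.size):
        if stim_t0[s] < t_next <= stim_t1[s]:
            rhs[stim_comp[s]] += stim_amp[s]
    for s in range(syn_comp.size):
        tt = t_next - syn_on[s]
        if tt <= 0.0:
            continue
        g = syn_g[s] * (np.exp(-tt / syn_taud[s]) - np.exp(-tt / syn_taur[s]))
        if g <= 0.0:
            continue
        c = syn_comp[s]
        if syn_vdep[s] == 1:
            g /= 1.0 + np.exp(-syn_gamma[s] * v[c]) * syn_nmg[s]
        d[c] += g
        rhs[c] += g * syn_e[s]


@njit(cache=True)
def run_passive(parent, g_ax, cm, g_pas, e_pas, dt, nsteps,
                stim_comp, stim_amp, stim_t0, stim_t1,
                syn_comp, syn_g, syn_taur, syn_taud, syn_on, syn_e,
                syn_vdep, syn_gamma, syn_nmg,
                v0, rec_idx):
    n = parent.size
    v = np.full(n, v0)
    d0 = _static_diag(parent, g_ax, cm, g_pas, dt)
    out = np.empty((rec_idx.size, nsteps + 1))
    for k in range(rec_idx.size):
        out[k, 0] = v[rec_idx[k]]
    d = np.empty(n)
    rhs = np.empty(n)
    for step in range(nsteps):
        t_next = (step + 1) * dt
        for i in range(n):
            d[i] = d0[i]
            rhs[i] = cm[i] / dt * v[i] + g_pas[i] * e_pas[i]
        _add_stimuli(t_next, d, rhs, v,
                     stim_comp, stim_amp, stim_t0, stim_t1,
                     syn_comp, syn_g, syn_taur, syn_taud, syn_on, syn_e,
                     syn_vdep, syn_gamma, syn_nmg)
        _hines_solve(parent, g_ax, d, rhs, v)
        for k in range(rec_idx.size):
            out[k, step + 1] = v[rec_idx[k]]
    return out


@njit(cache=True, inline="always")
def _gate_rates(kind, p, V, ca):
    """Steady state and time constant for one gate.

    Voltage gates: x∞ = 1/(1+exp(-(V-vh)/k)),
    τ(V) = τ_min + τ_amp / (exp((V-vt)/s1) + exp(-(V-vt)/s2)).
    Calcium gates: x∞ = ca^h/(ca^h + kd^h), fixed τ (p layout reused:
    vh=kd, k=h, tau_min=τ).
    """
    if kind == _GATE_CA:
        kd = p[0]
        h = p[1]
        ch = ca**h
        xinf = ch / (ch + kd**h)
        tau = p[2]
    else:
        xinf = 1.0 / (1.0 + np.exp(-(V - p[0]) / p[1]))
        tau = p[2] + p[3] / (np.exp((V - p[4]) / p[5]) + np.exp(-(V - p[4]) / p[6]))
    if tau < 1e-3:
        tau = 1e-3
    return xinf, tau


@njit(cache=True)
def run_active(parent, g_ax, cm, g_pas, e_pas, dt, nsteps,
               stim_comp, stim_amp, stim_t0, stim_t1,
               syn_comp, syn_g, syn_taur, syn_taud, syn_on, syn_e,
               syn_vdep, syn_gamma, syn_nmg,
               v0, rec_idx,
               act_comp, gbar,
               chan_erev, chan_is_ca, chan_ca_gated,
               gate_kind, gate_pow, gate_p,
               ca_gamma, ca_tau):
    """Active integration: HH-style channels on a subset of compartments.

    gbar: (nact, nchan) μS; gate_kind/gate_pow: (nact, nchan, 2);
    gate_p: (nact, nchan, 2, 7).  Gates advance by exponential Euler at the
    pre-step voltage; channel conductances then enter the implicit solve.
    A single-pool calcium concentration per active compartment drives
    Ca-gated channels.
    """
    n = parent.size
    nact = act_comp.size
    nchan = chan_erev.size
    v = np.full(n, v0)
    ca0 = 1e-4  # mM resting
    ca = np.full(nact, ca0)
    gates = np.empty((nact, nchan, 2))
    for k in range(nact):
        for c in range(nchan):
            for j in range(2):
                if gate_kind[k, c, j] == _GATE_OFF:
                    gates[k, c, j] = 1.0
                else:
                    xinf, _ = _gate_rates(gate_kind[k, c, j], gate_p[k, c, j], v0, ca0)
                    gates[k, c, j] = xinf
    d0 = _static_diag(parent, g_ax, cm, g_pas, dt)
    out = np.empty((rec_idx.size, nsteps + 1))
    for k in range(rec_idx.size):
        out[k, 0] = v[rec_idx[k]]
    d = np.empty(n)
    rhs = np.empty(n)
    i_ca = np.zeros(nact)
    for step in range(nsteps):
        t_next = (step + 1) * dt
        for i in range(n):
            d[i] = d0[i]
            rhs[i] = cm[i] / dt * v[i] + g_pas[i] * e_pas[i]
        _add_stimuli(t_next, d, rhs, v,
                     stim_comp, stim_amp, stim_t0, stim_t1,
                     syn_comp, syn_g, syn_taur, syn_taud, syn_on, syn_e,
                     syn_vdep, syn_gamma, syn_nmg)
        # channels
        for k in range(nact):
            comp = act_comp[k]
            V = v[comp]
            i_ca[k] = 0.0
            for c in range(nchan):
                if gbar[k, c] <= 0.0:
                    continue
                g = gbar[k, c]
                for j in range(2):
                    kind = gate_kind[k, c, j]
                    if kind == _GATE_OFF:
                        continue
                    xinf, tau = _gate_rates(kind, gate_p[k, c, j], V, ca[k])
                    x = gates[k, c, j] + (xinf - gates[k, c, j]) * (
                        1.0 - np.exp(-dt / tau))
                    gates[k, c, j] = x
                    for _rep in range(gate_pow[k, c, j]):
                        g *= x
                d[comp] += g
                rhs[comp] += g * chan_erev[c]
                if chan_is_ca[c] == 1:
                    i_ca[k] += g * (V - chan_erev[c])  # nA, pre-step voltage
        _hines_solve(parent, g_ax, d, rhs, v)
        # calcium pool: influx scaled by ca_gamma (mM per nA·ms), linear decay
        for k in range(nact):
            dca = -ca_gamma[k] * i_ca[k] - (ca[k] - ca0) / ca_tau[k]
            ca[k] += dt * dca
            if ca[k] < 1e-6:
                ca[k] = 1e-6
        for k in range(rec_idx.size):
            out[k, step + 1] = v[rec_idx[k]]
    return out
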