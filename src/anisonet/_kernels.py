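"""Numba inner loop for the LIF / alpha-synapse simulator.

State per neuron: membrane potential v, refractory countdown, and a single
cascaded alpha filter (y1, y2) shared by excitatory and inhibitory inputs
(both synapse classes use the same time constant; inputs differ only in the
sign of the impulse). The linear membrane+synapse subsystem is advanced by
its exact propagator each step; external current (noise + stimulus) is held
constant within a step. Spikes are detected on the grid at the end of the
step, reset to v_reset, clamped for the refractory period, and delivered to
targets through a ring buffer after the synaptic delay.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def run_lif(n_steps, dt, indptr, targets, w_syn, delay_steps,
            tau_m, c_m, e_l, v_th, v_reset, ref_steps, tau_s,
            mu, sigma, noise_steps, stim_amp, stim_start, stim_stop,
            v0, seed, capacity):
    n = v0.shape[0]
    np.random.seed(seed)

    e_s = np.exp(-dt / tau_s)
    e_m = np.exp(-dt / tau_m)
    g_l = c_m / tau_m
    a = 1.0 / tau_s - 1.0 / tau_m
    if abs(a) > 1e-12:
        p31 = (e_m * (1.0 - (1.0 + a * dt) * np.exp(-a * dt)) / (a * a)) / c_m
    else:
        p31 = e_m * dt * dt / 2.0 / c_m
    p32 = ((np.exp(-dt / tau_s) - e_m) / (1.0 / tau_m - 1.0 / tau_s)) / c_m
    p30 = (1.0 - e_m) / g_l

    v = v0.copy()
    y1 = np.zeros(n)
    y2 = np.zeros(n)
    ref = np.zeros(n, np.int64)
    buf = np.zeros((delay_steps, n))
    i_ext = np.zeros(n)

    cap = capacity
    sp_t = np.empty(cap)
    sp_i = np.empty(cap, np.int32)
    nsp = 0

    n_stim = stim_start.shape[0]
    si = 0
    for step in range(n_steps):
        slot = step % delay_steps
        if step % noise_steps == 0:
            for i in range(n):
                i_ext[i] = mu + sigma * np.random.normal()
        while si < n_stim and step >= stim_stop[si]:
            si += 1
        stim_on = si < n_stim and stim_start[si] <= step

        for i in range(n):
            y1i = y1[i] + buf[slot, i]
            buf[slot, i] = 0.0
            cur = i_ext[i]
            if stim_on:
                cur += stim_amp[i]
            v_new = e_l + (v[i] - e_l) * e_m + p31 * y1i + p32 * y2[i] + p30 * cur
            y2[i] = e_s * (y2[i] + dt * y1i)
            y1[i] = e_s * y1i
            if ref[i] > 0:
                ref[i] -= 1
                v[i] = v_reset
            else:
                v[i] = v_new
                if v[i] >= v_th:
                    if nsp == cap:
                        cap2 = cap * 2
                        t2 = np.empty(cap2)
                        i2 = np.empty(cap2, np.int32)
                        t2[:nsp] = sp_t[:nsp]
                        i2[:nsp] = sp_i[:nsp]
                        sp_t = t2
                        sp_i = i2
                        cap = cap2
                    sp_t[nsp] = (step + 1) * dt
                    sp_i[nsp] = i
                    nsp += 1
                    v[i] = v_reset
                    ref[i] = ref_steps
                    w = w_syn[i]
                    for k in range(indptr[i], indptr[i + 1]):
                        buf[slot, targets[k]] += w
    return sp_t[:nsp].copy(), sp_i[:nsp].copy(), v
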