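"""Compiled (numba) network integration kernel.

This duplicates the closed forms of `channels`/`cell` for speed; a unit test
pins the two paths together to machine precision on random states.  State
layout per cell matches ``cell.STATE_VARS``:

    0 v_dend, 1 v_soma, 2 v_axon, 3 r, 4 s, 5 q, 6 ca,
    7 k, 8 l, 9 h, 10 n, 11 x_s, 12 h_a, 13 x_a

Shared-parameter vector layout (``pack_params``):

    0 g_na_s  1 g_kdr_s  2 g_k_s  3 g_ls  4 g_cah  5 g_kca  6 g_h  7 g_ld
    8 g_na_a  9 g_k_a  10 g_la  11 g_int  12 p_soma_dend  13 p_axon_soma
    14 c_m  15 e_na  16 e_k  17 e_ca  18 e_h  19 e_leak
    20 ca_influx  21 ca_decay  22 g_gap  23 gap_voltage_dependent (0/1)
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

NSTATE = 14
NPARAM = 24


def pack_params(cp, g_gap: float, gap_voltage_dependent: bool) -> np.ndarray:
    p = np.array(
        [cp.g_na_s, cp.g_kdr_s, cp.g_k_s, cp.g_ls, cp.g_cah, cp.g_kca, cp.g_h, cp.g_ld,
         cp.g_na_a, cp.g_k_a, cp.g_la, cp.g_int, cp.p_soma_dend, cp.p_axon_soma,
         cp.c_m, cp.e_na, cp.e_k, cp.e_ca, cp.e_h, cp.e_leak,
         cp.ca_influx, cp.ca_decay, g_gap, 1.0 if gap_voltage_dependent else 0.0],
        dtype=np.float64,
    )
    return p


@njit(cache=True)
def _stim_eval(t, n_cells, st_cell, st_comp, st_kind, st_amp, st_on, st_dur,
               st_freq, st_phase, st_off, out_d, out_s):
    for i in range(n_cells):
        out_d[i] = 0.0
        out_s[i] = 0.0
    for e in range(st_cell.size):
        if st_on[e] <= t < st_on[e] + st_dur[e]:
            if st_kind[e] == 0:
                val = st_amp[e]
            else:
                # sinusoid in absolute time: amp·sin(2π f t/1000 + phase) + offset
                val = st_amp[e] * math.sin(
                    2.0 * math.pi * st_freq[e] * t * 1.0e-3 + st_phase[e]
                ) + st_off[e]
            c = st_cell[e]
            if st_comp[e] == 0:
                out_d[c] += val
            else:
                out_s[c] += val


@njit(cache=True)
def _deriv(y, gcal, P, indptr, indices, stim_d, stim_s, dy):
    n = y.shape[0]
    for i in range(n):
        vd = y[i, 0]
        vs = y[i, 1]
        va = y[i, 2]
        r = y[i, 3]
        s = y[i, 4]
        q = y[i, 5]
        ca = y[i, 6]
        k = y[i, 7]
        ll = y[i, 8]
        h = y[i, 9]
        nn = y[i, 10]
        xs = y[i, 11]
        ha = y[i, 12]
        xa = y[i, 13]

        # gap-junction current (outward-positive for cell i)
        igap = 0.0
        for jj in range(indptr[i], indptr[i + 1]):
            dvij = vd - y[indices[jj], 0]
            if P[23] > 0.5:
                f = 0.8 * math.exp(-dvij * dvij / 100.0) + 0.2
            else:
                f = 1.0
            igap += P[22] * f * dvij

        # dendrite
        i_cah = P[4] * r * r * (vd - P[17])
        i_kca = P[5] * s * (vd - P[16])
        i_h = P[6] * q * (vd - P[18])
        i_ld = P[7] * (vd - P[19])
        i_sd = (P[11] / (1.0 - P[12])) * (vd - vs)
        dy[i, 0] = (-(i_cah + i_kca + i_h + i_ld + i_sd + igap) + stim_d[i]) / P[14]

        # soma
        i_cal = gcal[i] * k * k * k * ll * (vs - P[17])
        m_inf = 1.0 / (1.0 + math.exp(-(vs + 30.0) / 5.5))
        i_na = P[0] * m_inf * m_inf * m_inf * h * (vs - P[15])
        i_kdr = P[1] * nn * nn * nn * nn * (vs - P[16])
        i_ks = P[2] * xs * xs * xs * xs * (vs - P[16])
        i_ls = P[3] * (vs - P[19])
        i_ds = (P[11] / P[12]) * (vs - vd)
        i_as = (P[11] / (1.0 - P[13])) * (vs - va)
        dy[i, 1] = (-(i_cal + i_na + i_kdr + i_ks + i_ls + i_ds + i_as) + stim_s[i]) / P[14]

        # axon hillock
        m_inf_a = 1.0 / (1.0 + math.exp(-(va + 30.0) / 5.5))
        i_na_a = P[8] * m_inf_a * m_inf_a * m_inf_a * ha * (va - P[15])
        i_ka = P[9] * xa * xa * xa * xa * (va - P[16])
        i_la = P[10] * (va - P[19])
        i_sa = (P[11] / P[13]) * (va - vs)
        dy[i, 2] = -(i_na_a + i_ka + i_la + i_sa) / P[14]

        # dendritic gates
        alpha_r = 1.7 / (1.0 + math.exp(-(vd - 5.0) / 13.9))
        xr = vd + 8.5
        if abs(xr) < 1e-9:
            beta_r = 0.02 * 5.0
        else:
            beta_r = 0.02 * xr / (math.exp(xr / 5.0) - 1.0)
        dy[i, 3] = (alpha_r / (alpha_r + beta_r) - r) * (alpha_r + beta_r) / 5.0

        alpha_s = 2.0e-5 * ca
        if alpha_s > 0.01:
            alpha_s = 0.01
        dy[i, 4] = (alpha_s / (alpha_s + 0.015) - s) * (alpha_s + 0.015)

        q_inf = 1.0 / (1.0 + math.exp((vd + 80.0) / 4.0))
        tau_q = 1.0 / (math.exp(-0.086 * vd - 14.6) + math.exp(0.070 * vd - 1.87))
        dy[i, 5] = (q_inf - q) / tau_q

        dy[i, 6] = -P[20] * i_cah - P[21] * ca

        # somatic gates
        k_inf = 1.0 / (1.0 + math.exp(-(vs + 61.0) / 4.2))
        dy[i, 7] = k_inf - k  # tau_k = 1 ms

        l_inf = 1.0 / (1.0 + math.exp((vs + 85.5) / 8.5))
        tau_l = 20.0 * math.exp((vs + 160.0) / 30.0) / (1.0 + math.exp((vs + 84.0) / 7.3)) + 35.0
        dy[i, 8] = (l_inf - ll) / tau_l

        h_inf = 1.0 / (1.0 + math.exp((vs + 70.0) / 5.8))
        tau_h = 3.0 * math.exp(-(vs + 40.0) / 33.0)
        dy[i, 9] = (h_inf - h) / tau_h

        n_inf = 1.0 / (1.0 + math.exp(-(vs + 3.0) / 10.0))
        tau_n = 5.0 + 47.0 * math.exp((vs + 50.0) / 900.0)
        dy[i, 10] = (n_inf - nn) / tau_n

        xv = vs + 25.0
        if abs(xv) < 1e-9:
            a_x = 0.13 * 10.0
        else:
            a_x = 0.13 * xv / (1.0 - math.exp(-xv / 10.0))
        b_x = 1.69 * math.exp(-0.0125 * (vs + 35.0))
        dy[i, 11] = (a_x / (a_x + b_x) - xs) * (a_x + b_x)

        # axonal gates
        h_inf_a = 1.0 / (1.0 + math.exp((va + 60.0) / 5.8))
        tau_h_a = 1.5 * math.exp(-(va + 40.0) / 33.0)
        dy[i, 12] = (h_inf_a - ha) / tau_h_a

        xva = va + 25.0
        if abs(xva) < 1e-9:
            a_xa = 0.13 * 10.0
        else:
            a_xa = 0.13 * xva / (1.0 - math.exp(-xva / 10.0))
        b_xa = 1.69 * math.exp(-0.0125 * (va + 35.0))
        dy[i, 13] = (a_xa / (a_xa + b_xa) - xa) * (a_xa + b_xa)


@njit(cache=True)
def integrate_rk4(y0, gcal, P, indptr, indices,
                  st_cell, st_comp, st_kind, st_amp, st_on, st_dur,
                  st_freq, st_phase, st_off,
                  dt, n_steps, rec_every, store_state, t0):
    """Fixed-step RK4.  Returns (V, S, y_final, status, fail_step).

    status 0 = ok; 1 = divergence (|V| > 150 mV or non-finite).
    V has shape (n_steps//rec_every + 1, n_cells, 3); S the full state
    history at the same times if ``store_state`` else a dummy (1,1,1) array.
    """
    n = y0.shape[0]
    n_rec = n_steps // rec_every + 1
    V = np.empty((n_rec, n, 3))
    if store_state:
        S = np.empty((n_rec, n, NSTATE))
    else:
        S = np.empty((1, 1, 1))
    y = y0.copy()
    k1 = np.empty((n, NSTATE))
    k2 = np.empty((n, NSTATE))
    k3 = np.empty((n, NSTATE))
    k4 = np.empty((n, NSTATE))
    yt = np.empty((n, NSTATE))
    sd = np.empty(n)
    ss = np.empty(n)
    sd2 = np.empty(n)
    ss2 = np.empty(n)

    for i in range(n):
        for c in range(3):
            V[0, i, c] = y[i, c]
    if store_state:
        S[0] = y

    status = 0
    fail_step = -1
    for step in range(n_steps):
        t = t0 + step * dt
        _stim_eval(t, n, st_cell, st_comp, st_kind, st_amp, st_on, st_dur,
                   st_freq, st_phase, st_off, sd, ss)
        _deriv(y, gcal, P, indptr, indices, sd, ss, k1)
        _stim_eval(t + 0.5 * dt, n, st_cell, st_comp, st_kind, st_amp, st_on, st_dur,
                   st_freq, st_phase, st_off, sd2, ss2)
        for i in range(n):
            for v in range(NSTATE):
                yt[i, v] = y[i, v] + 0.5 * dt * k1[i, v]
        _deriv(yt, gcal, P, indptr, indices, sd2, ss2, k2)
        for i in range(n):
            for v in range(NSTATE):
                yt[i, v] = y[i, v] + 0.5 * dt * k2[i, v]
        _deriv(yt, gcal, P, indptr, indices, sd2, ss2, k3)
        _stim_eval(t + dt, n, st_cell, st_comp, st_kind, st_amp, st_on, st_dur,
                   st_freq, st_phase, st_off, sd2, ss2)
        for i in range(n):
            for v in range(NSTATE):
                yt[i, v] = y[i, v] + dt * k3[i, v]
        _deriv(yt, gcal, P, indptr, indices, sd2, ss2, k4)
        for i in range(n):
            for v in range(NSTATE):
                y[i, v] = y[i, v] + (dt / 6.0) * (
                    k1[i, v] + 2.0 * k2[i, v] + 2.0 * k3[i, v] + k4[i, v]
                )

        ok = True
        for i in range(n):
            for c in range(3):
                vv = y[i, c]
                if not np.isfinite(vv) or vv > 150.0 or vv < -150.0:
                    ok = False
        if not ok:
            status = 1
            fail_step = step + 1
            break
        if (step + 1) % rec_every == 0:
            idx = (step + 1) // rec_every
            for i in range(n):
                for c in range(3):
                    V[idx, i, c] = y[i, c]
            if store_state:
                S[idx] = y

    return V, S, y, status, fail_step
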