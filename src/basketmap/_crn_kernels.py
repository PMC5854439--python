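"""Numba kernels for the CRN atrial membrane model.

Two entry points matter:

* :func:`crn_rhs` — the full right-hand side dstate/dt for one cell, used as
  the readable reference and for derivative-level checks.
* :func:`rush_larsen_step` — one Rush–Larsen (gates) / forward-Euler
  (voltage, concentrations) step, used by the single-cell pacing driver and
  by the tissue reaction step.

State layout (21 variables) follows ``crn_constants.STATE_NAMES``:
vm, m, h, j, oa, oi, ua, ui, xr, xs, d, f, f_ca, u, v, w,
na_i, k_i, ca_i, ca_up, ca_rel.

Conductance scalars are passed as a 6-vector in the order
(g_to, g_CaL, g_Kr, g_K1, g_Kur, g_Ks).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from . import crn_constants as C

RTF = C.R_GAS * C.TEMP / C.FARADAY  # ~26.71 mV
_SIGMA_NAK = (math.exp(C.NA_O / 67.3) - 1.0) / 7.0


@njit(cache=True, fastmath=False)
def _gate_rates(vm):
    """Voltage-dependent gate steady states and time constants.

    Returns two 13-vectors (inf, tau) for the gates
    m, h, j, oa, oi, ua, ui, xr, xs, d, f, w and a placeholder slot
    (the Ca- and Fn-dependent gates f_ca, u, v are handled separately).
    """
    inf = np.empty(12)
    tau = np.empty(12)

    # --- INa gates (m, h, j) ---------------------------------------------
    if abs(vm + 47.13) < 1e-10:
        a_m = 3.2
    else:
        a_m = 0.32 * (vm + 47.13) / (1.0 - math.exp(-0.1 * (vm + 47.13)))
    b_m = 0.08 * math.exp(-vm / 11.0)
    inf[0] = a_m / (a_m + b_m)
    tau[0] = 1.0 / (a_m + b_m)

    if vm >= -40.0:
        a_h = 0.0
        b_h = 1.0 / (0.13 * (1.0 + math.exp(-(vm + 10.66) / 11.1)))
        a_j = 0.0
        b_j = 0.3 * math.exp(-2.535e-7 * vm) / (1.0 + math.exp(-0.1 * (vm + 32.0)))
    else:
        a_h = 0.135 * math.exp(-(vm + 80.0) / 6.8)
        b_h = 3.56 * math.exp(0.079 * vm) + 3.1e5 * math.exp(0.35 * vm)
        a_j = ((-1.2714e5 * math.exp(0.2444 * vm) - 3.474e-5 * math.exp(-0.04391 * vm))
               * (vm + 37.78) / (1.0 + math.exp(0.311 * (vm + 79.23))))
        b_j = 0.1212 * math.exp(-0.01052 * vm) / (1.0 + math.exp(-0.1378 * (vm + 40.14)))
    inf[1] = a_h / (a_h + b_h)
    tau[1] = 1.0 / (a_h + b_h)
    inf[2] = a_j / (a_j + b_j)
    tau[2] = 1.0 / (a_j + b_j)

    # --- Ito gates (oa, oi) ----------------------------------------------
    a_oa = 0.65 / (math.exp(-(vm + 10.0) / 8.5) + math.exp(-(vm - 30.0) / 59.0))
    b_oa = 0.65 / (2.5 + math.exp((vm + 82.0) / 17.0))
    inf[3] = 1.0 / (1.0 + math.exp(-(vm + 20.47) / 17.54))
    tau[3] = 1.0 / ((a_oa + b_oa) * C.KQ10)

    a_oi = 1.0 / (18.53 + math.exp((vm + 113.7) / 10.95))
    b_oi = 1.0 / (35.56 + math.exp(-(vm + 1.26) / 7.44))
    inf[4] = 1.0 / (1.0 + math.exp((vm + 43.1) / 5.3))
    tau[4] = 1.0 / ((a_oi + b_oi) * C.KQ10)

    # --- IKur gates (ua, ui) ---------------------------------------------
    a_ua = 0.65 / (math.exp(-(vm + 10.0) / 8.5) + math.exp(-(vm - 30.0) / 59.0))
    b_ua = 0.65 / (2.5 + math.exp((vm + 82.0) / 17.0))
    inf[5] = 1.0 / (1.0 + math.exp(-(vm + 30.3) / 9.6))
    tau[5] = 1.0 / ((a_ua + b_ua) * C.KQ10)

    a_ui = 1.0 / (21.0 + math.exp(-(vm - 185.0) / 28.0))
    b_ui = math.exp((vm - 158.0) / 16.0)
    inf[6] = 1.0 / (1.0 + math.exp((vm - 99.45) / 27.48))
    tau[6] = 1.0 / ((a_ui + b_ui) * C.KQ10)

    # --- IKr gate (xr) ----------------------------------------------------
    if abs(vm + 14.1) < 1e-10:
        a_xr = 0.0015
    else:
        a_xr = 0.0003 * (vm + 14.1) / (1.0 - math.exp(-(vm + 14.1) / 5.0))
    if abs(vm - 3.3328) < 1e-10:
        b_xr = 3.7836118e-4
    else:
        b_xr = 7.3898e-5 * (vm - 3.3328) / (math.exp((vm - 3.3328) / 5.1237) - 1.0)
    inf[7] = 1.0 / (1.0 + math.exp(-(vm + 14.1) / 6.5))
    tau[7] = 1.0 / (a_xr + b_xr)

    # --- IKs gate (xs) ----------------------------------------------------
    if abs(vm - 19.9) < 1e-10:
        a_xs = 6.8e-4
        b_xs = 3.15e-4
    else:
        a_xs = 4e-5 * (vm - 19.9) / (1.0 - math.exp(-(vm - 19.9) / 17.0))
        b_xs = 3.5e-5 * (vm - 19.9) / (math.exp((vm - 19.9) / 9.0) - 1.0)
    inf[8] = 1.0 / math.sqrt(1.0 + math.exp(-(vm - 19.9) / 12.7))
    tau[8] = 0.5 / (a_xs + b_xs)

    # --- ICaL gates (d, f) ------------------------------------------------
    inf[9] = 1.0 / (1.0 + math.exp(-(vm + 10.0) / 8.0))
    if abs(vm + 10.0) < 1e-10:
        tau[9] = 1.0 / (0.035 * 6.24 * 2.0)
    else:
        e1 = math.exp(-(vm + 10.0) / 6.24)
        tau[9] = (1.0 - e1) / (0.035 * (vm + 10.0) * (1.0 + e1))
    inf[10] = 1.0 / (1.0 + math.exp((vm + 28.0) / 6.9))
    tau[10] = 9.0 / (0.0197 * math.exp(-(0.0337 ** 2) * (vm + 10.0) ** 2) + 0.02)

    # --- SR release voltage gate (w) -------------------------------------
    inf[11] = 1.0 - 1.0 / (1.0 + math.exp(-(vm - 40.0) / 17.0))
    if abs(vm - 7.9) < 1e-10:
        tau[11] = 6.0 / (5.0 * 1.3)
    else:
        e2 = math.exp(-(vm - 7.9) / 5.0)
        tau[11] = 6.0 * (1.0 - e2) / ((1.0 + 0.3 * e2) * (vm - 7.9))

    return inf, tau


@njit(cache=True, fastmath=False)
def _currents(state, scalars):
    """All membrane currents (pA/pF) plus SR fluxes for the current state.

    Returns (i_ion_total, i_na, i_k1, i_to, i_kur, i_kr, i_ks, i_cal,
    i_pca, i_nak, i_naca, i_bna, i_bca, i_rel, i_tr, i_up, i_upleak).
    """
    vm = state[0]
    m = state[1]; h = state[2]; j = state[3]
    oa = state[4]; oi = state[5]; ua = state[6]; ui = state[7]
    xr = state[8]; xs = state[9]
    d = state[10]; f = state[11]; f_ca = state[12]
    u = state[13]; v = state[14]; w = state[15]
    na_i = state[16]; k_i = state[17]; ca_i = state[18]
    ca_up = state[19]; ca_rel = state[20]

    s_to = scalars[0]; s_cal = scalars[1]; s_kr = scalars[2]
    s_k1 = scalars[3]; s_kur = scalars[4]; s_ks = scalars[5]

    e_na = RTF * math.log(C.NA_O / na_i)
    e_k = RTF * math.log(C.K_O / k_i)
    e_ca = 0.5 * RTF * math.log(C.CA_O / ca_i)

    i_na = C.G_NA * m ** 3 * h * j * (vm - e_na)
    i_k1 = s_k1 * C.G_K1 * (vm - e_k) / (1.0 + math.exp(0.07 * (vm + 80.0)))
    i_to = s_to * C.G_TO * oa ** 3 * oi * (vm - e_k)
    g_kur = 0.005 + 0.05 / (1.0 + math.exp(-(vm - 15.0) / 13.0))
    i_kur = s_kur * g_kur * ua ** 3 * ui * (vm - e_k)
    i_kr = s_kr * C.G_KR * xr * (vm - e_k) / (1.0 + math.exp((vm + 15.0) / 22.4))
    i_ks = s_ks * C.G_KS * xs ** 2 * (vm - e_k)
    i_cal = s_cal * C.G_CAL * d * f * f_ca * (vm - 65.0)

    f_nak = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * vm / RTF)
                   + 0.0365 * _SIGMA_NAK * math.exp(-vm / RTF))
    i_nak = (C.I_NAK_MAX * f_nak * C.K_O / (C.K_O + C.KM_K_O)
             / (1.0 + (C.KM_NA_I / na_i) ** 1.5))

    ex_g = math.exp(C.GAMMA * vm / RTF)
    ex_g1 = math.exp((C.GAMMA - 1.0) * vm / RTF)
    i_naca = (C.I_NACA_MAX
              * (ex_g * na_i ** 3 * C.CA_O - ex_g1 * C.NA_O ** 3 * ca_i)
              / ((C.KM_NA ** 3 + C.NA_O ** 3) * (C.KM_CA + C.CA_O)
                 * (1.0 + C.K_SAT * ex_g1)))

    i_pca = C.I_PCA_MAX * ca_i / (0.0005 + ca_i)
    i_bna = C.G_B_NA * (vm - e_na)
    i_bca = C.G_B_CA * (vm - e_ca)

    i_rel = C.K_REL * u ** 2 * v * w * (ca_rel - ca_i)
    i_tr = (ca_up - ca_rel) / C.TAU_TR
    i_up = C.I_UP_MAX / (1.0 + C.K_UP / ca_i)
    i_upleak = C.I_UP_MAX * ca_up / C.CA_UP_MAX

    i_ion = (i_na + i_k1 + i_to + i_kur + i_kr + i_ks + i_cal
             + i_pca + i_nak + i_naca + i_bna + i_bca)

    return (i_ion, i_na, i_k1, i_to, i_kur, i_kr, i_ks, i_cal,
            i_pca, i_nak, i_naca, i_bna, i_bca, i_rel, i_tr, i_up, i_upleak)


@njit(cache=True, fastmath=False)
def _fn_gates(i_rel, i_cal, i_naca):
    """Steady states / time constants of the Fn-controlled SR gates u, v."""
    fn = (1e-12 * C.V_REL * i_rel
          - (5e-13 / C.FARADAY) * (0.5 * i_cal - 0.2 * i_naca) * C.CM_PF)
    u_inf = 1.0 / (1.0 + math.exp(-(fn - 3.4175e-13) / 1.367e-15))
    v_inf = 1.0 - 1.0 / (1.0 + math.exp(-(fn - 6.835e-14) / 1.367e-15))
    tau_v = 1.91 + 2.09 / (1.0 + math.exp(-(fn - 3.4175e-13) / 1.367e-15))
    return u_inf, v_inf, tau_v


@njit(cache=True, fastmath=False)
def crn_rhs(state, scalars, i_stim):
    """Full dstate/dt (units per ms).  ``i_stim`` in pA/pF, inward negative."""
    out = np.empty(C.STATE_DIM)
    cur = _currents(state, scalars)
    i_ion = cur[0]
    i_cal = cur[7]; i_pca = cur[8]; i_nak = cur[9]; i_naca = cur[10]
    i_na = cur[1]; i_k1 = cur[2]; i_to = cur[3]; i_kur = cur[4]
    i_kr = cur[5]; i_ks = cur[6]; i_bna = cur[11]; i_bca = cur[12]
    i_rel = cur[13]; i_tr = cur[14]; i_up = cur[15]; i_upleak = cur[16]

    out[0] = -(i_ion + i_stim)

    inf, tau = _gate_rates(state[0])
    # gates m..f occupy state indices 1..11; w is index 15
    for g in range(11):
        out[1 + g] = (inf[g] - state[1 + g]) / tau[g]
    out[15] = (inf[11] - state[15]) / tau[11]

    # f_ca gate (Ca-dependent)
    f_ca_inf = 1.0 / (1.0 + state[18] / 0.00035)
    out[12] = (f_ca_inf - state[12]) / C.TAU_F_CA

    # u, v gates (Fn-dependent)
    u_inf, v_inf, tau_v = _fn_gates(i_rel, i_cal, i_naca)
    out[13] = (u_inf - state[13]) / C.TAU_U
    out[14] = (v_inf - state[14]) / tau_v

    # concentrations
    fv = C.FARADAY * C.V_I
    out[16] = (-3.0 * i_nak - 3.0 * i_naca - i_bna - i_na) * C.CM_PF / fv
    out[17] = (2.0 * i_nak - i_k1 - i_to - i_kur - i_kr - i_ks) * C.CM_PF / fv

    ca_i = state[18]
    b1 = ((2.0 * i_naca - i_pca - i_cal - i_bca) * C.CM_PF / (2.0 * fv)
          + (C.V_UP * (i_upleak - i_up) + i_rel * C.V_REL) / C.V_I)
    b2 = (1.0
          + C.TRPN_MAX * C.KM_TRPN / (ca_i + C.KM_TRPN) ** 2
          + C.CMDN_MAX * C.KM_CMDN / (ca_i + C.KM_CMDN) ** 2)
    out[18] = b1 / b2
    out[19] = i_up - i_upleak - i_tr * C.V_REL / C.V_UP
    out[20] = ((i_tr - i_rel)
               / (1.0 + C.CSQN_MAX * C.KM_CSQN / (state[20] + C.KM_CSQN) ** 2))
    return out


@njit(cache=True, fastmath=False)
def rush_larsen_step(state, scalars, i_stim, dt):
    """Advance one cell by ``dt`` in place.

    Gates use the exponential Rush–Larsen update (exact for frozen rates);
    vm and concentrations use forward Euler.
    """
    cur = _currents(state, scalars)
    i_ion = cur[0]
    i_na = cur[1]; i_k1 = cur[2]; i_to = cur[3]; i_kur = cur[4]
    i_kr = cur[5]; i_ks = cur[6]; i_cal = cur[7]
    i_pca = cur[8]; i_nak = cur[9]; i_naca = cur[10]
    i_bna = cur[11]; i_bca = cur[12]
    i_rel = cur[13]; i_tr = cur[14]; i_up = cur[15]; i_upleak = cur[16]

    inf, tau = _gate_rates(state[0])
    for g in range(11):
        state[1 + g] = inf[g] + (state[1 + g] - inf[g]) * math.exp(-dt / tau[g])
    state[15] = inf[11] + (state[15] - inf[11]) * math.exp(-dt / tau[11])

    f_ca_inf = 1.0 / (1.0 + state[18] / 0.00035)
    state[12] = f_ca_inf + (state[12] - f_ca_inf) * math.exp(-dt / C.TAU_F_CA)

    u_inf, v_inf, tau_v = _fn_gates(i_rel, i_cal, i_naca)
    state[13] = u_inf + (state[13] - u_inf) * math.exp(-dt / C.TAU_U)
    state[14] = v_inf + (state[14] - v_inf) * math.exp(-dt / tau_v)

    fv = C.FARADAY * C.V_I
    state[16] += dt * (-3.0 * i_nak - 3.0 * i_naca - i_bna - i_na) * C.CM_PF / fv
    state[17] += dt * (2.0 * i_nak - i_k1 - i_to - i_kur - i_kr - i_ks) * C.CM_PF / fv

    ca_i = state[18]
    b1 = ((2.0 * i_naca - i_pca - i_cal - i_bca) * C.CM_PF / (2.0 * fv)
          + (C.V_UP * (i_upleak - i_up) + i_rel * C.V_REL) / C.V_I)
    b2 = (1.0
          + C.TRPN_MAX * C.KM_TRPN / (ca_i + C.KM_TRPN) ** 2
          + C.CMDN_MAX * C.KM_CMDN / (ca_i + C.KM_CMDN) ** 2)
    state[18] += dt * b1 / b2
    state[19] += dt * (i_up - i_upleak - i_tr * C.V_REL / C.V_UP)
    state[20] += dt * ((i_tr - i_rel)
                       / (1.0 + C.CSQN_MAX * C.KM_CSQN
                          / (state[20] + C.KM_CSQN) ** 2))

    state[0] += dt * (-(i_ion + i_stim))


@njit(cache=True, fastmath=False)
def pace_cell(state, scalars, dt, n_beats, bcl, stim_amplitude, stim_duration,
              record_stride):
    """Apply a pacing train and record vm.

    ``stim_amplitude`` is the signed current in pA/pF (depolarizing stimuli
    are negative).  Returns (times_ms, vm) sampled every ``record_stride``
    steps, and leaves ``state`` at the end of the run.  Raises no exceptions;
    on numerical blow-up the trace is truncated and vm[-1] set to NaN by the
    caller's contract (detected via |vm| > 200).
    """
    steps_per_beat = int(round(bcl / dt))
    n_steps = steps_per_beat * n_beats
    n_rec = n_steps // record_stride + 1
    times = np.empty(n_rec)
    vm = np.empty(n_rec)
    times[0] = 0.0
    vm[0] = state[0]
    k = 1
    stim_steps = int(round(stim_duration / dt))
    ok = True
    for i in range(n_steps):
        phase = i % steps_per_beat
        stim = stim_amplitude if phase < stim_steps else 0.0
        rush_larsen_step(state, scalars, stim, dt)
        if abs(state[0]) > 200.0 or not math.isfinite(state[0]):
            ok = False
            break
        if (i + 1) % record_stride == 0:
            times[k] = (i + 1) * dt
            vm[k] = state[0]
            k += 1
    return times[:k], vm[:k], ok
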