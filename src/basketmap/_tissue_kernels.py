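"""Numba kernels for the monodomain tissue solver.

The reaction step uses a voltage-indexed lookup table for every purely
voltage-dependent quantity of the CRN model (gate steady states, Rush–Larsen
exponential factors with the time step baked in, and the V-dependent factors
of IK1, IKur, IKr, INaK and INaCa).  Reversal potentials are refreshed every
``EREV_REFRESH`` steps — intracellular concentrations drift on a seconds
time scale, so this introduces no measurable error while removing three
logarithms per node per step.

Diffusion is an explicit face-weighted stencil: per node, up to four
neighbor links with precomputed weights w = D_face / dx^2 (harmonic-mean
face diffusivity); absent links (boundary, obstacle) simply carry no flux,
which makes the no-flux condition exact on the discrete stencil.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from . import crn_constants as C
from ._crn_kernels import _gate_rates, RTF, _SIGMA_NAK

EREV_REFRESH = 16
N_COLS = 30


@njit(cache=True)
def build_tables(dt, v_min, v_max, dv):
    """Tabulate V-dependent model quantities for time step ``dt``.

    Columns 0..23: (inf, exp(-dt/tau)) per gate in kernel order
    (m h j oa oi ua ui xr xs d f w); 24: IK1 voltage factor; 25: g_Kur(V);
    26: IKr rectification factor; 27: f_NaK; 28: exp(gamma*V*F/RT);
    29: exp((gamma-1)*V*F/RT).
    """
    n = int(round((v_max - v_min) / dv)) + 1
    tab = np.empty((n, N_COLS))
    for i in range(n):
        vm = v_min + i * dv
        inf, tau = _gate_rates(vm)
        for g in range(12):
            tab[i, 2 * g] = inf[g]
            tab[i, 2 * g + 1] = math.exp(-dt / tau[g])
        tab[i, 24] = 1.0 / (1.0 + math.exp(0.07 * (vm + 80.0)))
        tab[i, 25] = 0.005 + 0.05 / (1.0 + math.exp(-(vm - 15.0) / 13.0))
        tab[i, 26] = 1.0 / (1.0 + math.exp((vm + 15.0) / 22.4))
        tab[i, 27] = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * vm / RTF)
                            + 0.0365 * _SIGMA_NAK * math.exp(-vm / RTF))
        tab[i, 28] = math.exp(C.GAMMA * vm / RTF)
        tab[i, 29] = math.exp((C.GAMMA - 1.0) * vm / RTF)
    return tab


@njit(cache=True, fastmath=True)
def _reaction_step_tabled(states, scalars, region_idx, stim, erev, dt,
                          tab, v_min, inv_dv, exp_dt_fca, exp_dt_u):
    """One Rush–Larsen reaction step for all nodes, table-accelerated.

    Mirrors ``_crn_kernels.rush_larsen_step`` exactly up to table
    interpolation error.  ``stim`` is the per-node stimulus (pA/pF, inward
    negative); ``erev`` caches (e_na, e_k, e_ca) per node.
    """
    n_rows = tab.shape[0]
    for p in range(states.shape[0]):
        s = states[p]
        vm = s[0]
        pos = (vm - v_min) * inv_dv
        if pos < 0.0:
            pos = 0.0
        elif pos > n_rows - 1.001:
            pos = n_rows - 1.001
        i = int(pos)
        fr = pos - i
        r0 = tab[i]
        r1 = tab[i + 1]

        e_na = erev[p, 0]
        e_k = erev[p, 1]
        e_ca = erev[p, 2]
        na_i = s[16]
        ca_i = s[18]
        ca_rel = s[20]
        sc = scalars[region_idx[p]]

        ik1f = r0[24] + fr * (r1[24] - r0[24])
        gkur = r0[25] + fr * (r1[25] - r0[25])
        ikrf = r0[26] + fr * (r1[26] - r0[26])
        fnak = r0[27] + fr * (r1[27] - r0[27])
        ex_g = r0[28] + fr * (r1[28] - r0[28])
        ex_g1 = r0[29] + fr * (r1[29] - r0[29])

        m = s[1]; h = s[2]; j = s[3]
        i_na = C.G_NA * m * m * m * h * j * (vm - e_na)
        i_k1 = sc[3] * C.G_K1 * (vm - e_k) * ik1f
        oa = s[4]
        i_to = sc[0] * C.G_TO * oa * oa * oa * s[5] * (vm - e_k)
        ua = s[6]
        i_kur = sc[4] * gkur * ua * ua * ua * s[7] * (vm - e_k)
        i_kr = sc[2] * C.G_KR * s[8] * (vm - e_k) * ikrf
        xs = s[9]
        i_ks = sc[5] * C.G_KS * xs * xs * (vm - e_k)
        i_cal = sc[1] * C.G_CAL * s[10] * s[11] * s[12] * (vm - 65.0)
        i_nak = (C.I_NAK_MAX * fnak * C.K_O / (C.K_O + C.KM_K_O)
                 / (1.0 + (C.KM_NA_I / na_i) ** 1.5))
        i_naca = (C.I_NACA_MAX
                  * (ex_g * na_i ** 3 * C.CA_O - ex_g1 * C.NA_O ** 3 * ca_i)
                  / ((C.KM_NA ** 3 + C.NA_O ** 3) * (C.KM_CA + C.CA_O)
                     * (1.0 + C.K_SAT * ex_g1)))
        i_pca = C.I_PCA_MAX * ca_i / (0.0005 + ca_i)
        i_bna = C.G_B_NA * (vm - e_na)
        i_bca = C.G_B_CA * (vm - e_ca)

        u = s[13]
        i_rel = C.K_REL * u * u * s[14] * s[15] * (ca_rel - ca_i)
        i_tr = (s[19] - ca_rel) / C.TAU_TR
        i_up = C.I_UP_MAX / (1.0 + C.K_UP / ca_i)
        i_upleak = C.I_UP_MAX * s[19] / C.CA_UP_MAX

        i_ion = (i_na + i_k1 + i_to + i_kur + i_kr + i_ks + i_cal
                 + i_pca + i_nak + i_naca + i_bna + i_bca)

        # gates: Rush-Larsen with tabled inf / exp factors
        for g in range(11):
            inf = r0[2 * g] + fr * (r1[2 * g] - r0[2 * g])
            ed = r0[2 * g + 1] + fr * (r1[2 * g + 1] - r0[2 * g + 1])
            s[1 + g] = inf + (s[1 + g] - inf) * ed
        inf_w = r0[22] + fr * (r1[22] - r0[22])
        ed_w = r0[23] + fr * (r1[23] - r0[23])
        s[15] = inf_w + (s[15] - inf_w) * ed_w

        f_ca_inf = 1.0 / (1.0 + ca_i / 0.00035)
        s[12] = f_ca_inf + (s[12] - f_ca_inf) * exp_dt_fca

        fn = (1e-12 * C.V_REL * i_rel
              - (5e-13 / C.FARADAY) * (0.5 * i_cal - 0.2 * i_naca) * C.CM_PF)
        au = (fn - 3.4175e-13) / 1.367e-15
        if au > 35.0:
            u_inf = 1.0
            sig_u = 1.0
        elif au < -35.0:
            u_inf = 0.0
            sig_u = 0.0
        else:
            sig_u = 1.0 / (1.0 + math.exp(-au))
            u_inf = sig_u
        av = (fn - 6.835e-14) / 1.367e-15
        if av > 35.0:
            v_inf = 0.0
        elif av < -35.0:
            v_inf = 1.0
        else:
            v_inf = 1.0 - 1.0 / (1.0 + math.exp(-av))
        tau_v = 1.91 + 2.09 * sig_u
        s[13] = u_inf + (s[13] - u_inf) * exp_dt_u
        s[14] = v_inf + (s[14] - v_inf) * math.exp(-dt / tau_v)

        fv = C.FARADAY * C.V_I
        s[16] += dt * (-3.0 * i_nak - 3.0 * i_naca - i_bna - i_na) * C.CM_PF / fv
        s[17] += dt * (2.0 * i_nak - i_k1 - i_to - i_kur - i_kr - i_ks) * C.CM_PF / fv
        b1 = ((2.0 * i_naca - i_pca - i_cal - i_bca) * C.CM_PF / (2.0 * fv)
              + (C.V_UP * (i_upleak - i_up) + i_rel * C.V_REL) / C.V_I)
        b2 = (1.0
              + C.TRPN_MAX * C.KM_TRPN / (ca_i + C.KM_TRPN) ** 2
              + C.CMDN_MAX * C.KM_CMDN / (ca_i + C.KM_CMDN) ** 2)
        s[18] += dt * b1 / b2
        s[19] += dt * (i_up - i_upleak - i_tr * C.V_REL / C.V_UP)
        s[20] += dt * ((i_tr - i_rel)
                       / (1.0 + C.CSQN_MAX * C.KM_CSQN
                          / (ca_rel + C.KM_CSQN) ** 2))

        s[0] = vm + dt * (-(i_ion + stim[p]))


@njit(cache=True, fastmath=True)
def _refresh_erev(states, erev):
    for p in range(states.shape[0]):
        erev[p, 0] = RTF * math.log(C.NA_O / states[p, 16])
        erev[p, 1] = RTF * math.log(C.K_O / states[p, 17])
        erev[p, 2] = 0.5 * RTF * math.log(C.CA_O / states[p, 18])


@njit(cache=True, fastmath=True)
def _diffusion_step(states, nb_idx, nb_w, vm_old, dt):
    for p in range(states.shape[0]):
        vm_old[p] = states[p, 0]
    for p in range(states.shape[0]):
        acc = 0.0
        for k in range(nb_idx.shape[1]):
            q = nb_idx[p, k]
            if q >= 0:
                acc += nb_w[p, k] * (vm_old[q] - vm_old[p])
        states[p, 0] += dt * acc


@njit(cache=True, fastmath=True)
def run_monodomain(states, scalars, region_idx, nb_idx, nb_w,
                   stim_nodes, stim_offsets, stim_params, dt, n_steps,
                   record_every, frames, tab, v_min, inv_dv):
    """Operator-split (Godunov) monodomain integration.

    Stimulus ``si`` targets nodes ``stim_nodes[stim_offsets[si]:
    stim_offsets[si+1]]``; ``stim_params`` rows are (onset_ms,
    period_ms_or_0, duration_ms, count, amplitude_pA_per_pF).  ``frames`` is
    a preallocated (n_frames, n_nodes) float32 array filled with vm every
    ``record_every`` steps (frame 0 = initial state).  Returns the index of
    the first step at which |vm| exceeded 200 mV, or -1 if stable.
    """
    n_nodes = states.shape[0]
    stim = np.zeros(n_nodes)
    erev = np.empty((n_nodes, 3))
    vm_old = np.empty(n_nodes)
    _refresh_erev(states, erev)
    exp_dt_fca = math.exp(-dt / C.TAU_F_CA)
    exp_dt_u = math.exp(-dt / C.TAU_U)

    frames[0, :] = states[:, 0]
    fi = 1
    for step in range(n_steps):
        t = step * dt
        any_stim = False
        for si in range(stim_params.shape[0]):
            onset = stim_params[si, 0]
            period = stim_params[si, 1]
            dur = stim_params[si, 2]
            count = stim_params[si, 3]
            amp = stim_params[si, 4]
            if t < onset:
                continue
            if period <= 0.0:
                active = t < onset + dur
            else:
                k = math.floor((t - onset) / period)
                active = (k < count) and (t - onset - k * period) < dur
            if active:
                any_stim = True
                for q in range(stim_offsets[si], stim_offsets[si + 1]):
                    stim[stim_nodes[q]] += amp
        if step % EREV_REFRESH == 0:
            _refresh_erev(states, erev)
        _reaction_step_tabled(states, scalars, region_idx, stim, erev, dt,
                              tab, v_min, inv_dv, exp_dt_fca, exp_dt_u)
        if any_stim:
            for q in range(stim_nodes.shape[0]):
                stim[stim_nodes[q]] = 0.0
        _diffusion_step(states, nb_idx, nb_w, vm_old, dt)
        if (step + 1) % record_every == 0 and fi < frames.shape[0]:
            frames[fi, :] = states[:, 0]
            fi += 1
        if (step & 1023) == 0:
            bad = False
            for p in range(n_nodes):
                if not (abs(states[p, 0]) <= 200.0):
                    bad = True
                    break
            if bad:
                return step
    return -1
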