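"""Baseline constants of the Courtemanche–Ramírez–Nattel (CRN) human atrial
myocyte model, plus the regional conductance-scaling table and the chronic-AF
(cAF) remodeling multipliers.

Every number the membrane kinetics depend on lives in this module so the
parameterization is auditable in one place.  Units follow the original model:
mV, ms, mM, pA/pF; conductances in nS/pF.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Physical constants and cell geometry
# ---------------------------------------------------------------------------
R_GAS = 8.3143          # J mol^-1 K^-1
TEMP = 310.0            # K
FARADAY = 96.4867       # C mmol^-1
CM_PF = 100.0           # whole-cell membrane capacitance, pF

V_CELL = 20100.0        # cell volume, um^3
V_I = 13668.0           # intracellular (myoplasmic) volume, um^3
V_UP = 1109.52          # SR uptake compartment volume, um^3
V_REL = 96.48           # SR release compartment volume, um^3

# ---------------------------------------------------------------------------
# Extracellular ion concentrations (mM)
# ---------------------------------------------------------------------------
K_O = 5.4
NA_O = 140.0
CA_O = 1.8

# ---------------------------------------------------------------------------
# Maximal conductances (nS/pF) and pump/exchanger parameters
# ---------------------------------------------------------------------------
G_NA = 7.8
G_K1 = 0.09
G_TO = 0.1652
G_KR = 0.029411765
G_KS = 0.12941176
G_CAL = 0.12375
G_B_CA = 0.001131
G_B_NA = 0.0006744375

I_NAK_MAX = 0.59933874  # pA/pF
KM_NA_I = 10.0          # mM, Na+ half-saturation of INaK
KM_K_O = 1.5            # mM, K+ half-saturation of INaK

I_NACA_MAX = 1600.0     # pA/pF
KM_NA = 87.5            # mM
KM_CA = 1.38            # mM
K_SAT = 0.1
GAMMA = 0.35

I_PCA_MAX = 0.275       # pA/pF

# ---------------------------------------------------------------------------
# Intracellular Ca2+ handling
# ---------------------------------------------------------------------------
K_REL = 30.0            # ms^-1, maximal SR release rate
K_UP = 0.00092          # mM, half-saturation of SERCA uptake
I_UP_MAX = 0.005        # mM/ms
CA_UP_MAX = 15.0        # mM
TAU_TR = 180.0          # ms, uptake->release transfer time constant
TAU_F_CA = 2.0          # ms
TAU_U = 8.0             # ms

CMDN_MAX = 0.05         # mM, calmodulin
TRPN_MAX = 0.07         # mM, troponin
CSQN_MAX = 10.0         # mM, calsequestrin
KM_CMDN = 0.00238       # mM
KM_TRPN = 0.0005        # mM
KM_CSQN = 0.8           # mM

KQ10 = 3.0              # temperature scaling of Ito/IKur gate kinetics

# ---------------------------------------------------------------------------
# Initial (quiescent) state of the baseline model.  Order defines the state
# vector layout used throughout the package.
# ---------------------------------------------------------------------------
STATE_NAMES = (
    "vm", "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs",
    "d", "f", "f_ca", "u", "v", "w", "na_i", "k_i", "ca_i",
    "ca_up", "ca_rel",
)
STATE_DIM = len(STATE_NAMES)

INITIAL_STATE = {
    "vm": -81.18,
    "m": 2.908e-3,
    "h": 9.649e-1,
    "j": 9.775e-1,
    "oa": 3.043e-2,
    "oi": 9.992e-1,
    "ua": 4.966e-3,
    "ui": 9.986e-1,
    "xr": 3.296e-5,
    "xs": 1.869e-2,
    "d": 1.367e-4,
    "f": 9.996e-1,
    "f_ca": 7.755e-1,
    "u": 0.0,
    "v": 1.0,
    "w": 9.992e-1,
    "na_i": 11.17,
    "k_i": 139.0,
    "ca_i": 1.013e-4,
    "ca_up": 1.488,
    "ca_rel": 1.488,
}

# ---------------------------------------------------------------------------
# Regional heterogeneity: dimensionless multipliers on the maximal
# conductances of I_to, I_CaL and I_Kr per atrial region (control condition).
# RA_PM is the unmodified baseline model.
# ---------------------------------------------------------------------------
REGION_TAGS = (
    "RA_PM", "CT_BBRA", "TVR", "RAA", "LA", "BBLA", "MVR", "LAA", "PV",
)

#                 g_to   g_CaL  g_Kr
REGION_SCALARS = {
    "RA_PM":   (1.00, 1.00, 1.00),
    "CT_BBRA": (1.00, 1.67, 1.00),
    "TVR":     (1.00, 0.67, 1.53),
    "RAA":     (0.68, 1.00, 1.00),
    "LA":      (1.00, 1.00, 1.60),
    "BBLA":    (1.00, 1.67, 1.60),
    "MVR":     (1.00, 0.67, 2.44),
    "LAA":     (0.68, 1.00, 1.60),
    "PV":      (1.00, 1.00, 2.20),
}

# Regions remodeled with the right-atrial cAF profile; the rest use the
# left-atrial profile.
RA_FAMILY = frozenset({"RA_PM", "CT_BBRA", "TVR", "RAA"})
LA_FAMILY = frozenset({"LA", "BBLA", "MVR", "LAA", "PV"})

# cAF remodeling multipliers applied on top of the regional scalars.
#                 g_to   g_CaL  g_K1  g_Kur  g_Ks
CAF_MULTIPLIERS = {
    "RA": {"g_to": 0.55, "g_CaL": 0.35, "g_K1": 2.0, "g_Kur": 0.40, "g_Ks": 2.5},
    "LA": {"g_to": 0.25, "g_CaL": 0.35, "g_K1": 2.0, "g_Kur": 0.55, "g_Ks": 2.0},
}

SCALAR_CHANNELS = ("g_to", "g_CaL", "g_Kr", "g_K1", "g_Kur", "g_Ks")
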