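"""Numba-compiled right-hand sides for the RB-E2F ODE system.

The kernels are kept free of Python objects so the LSODA driver in
:func:`scipy.integrate.odeint` can call them cheaply inside the adaptive
walk, where a single objective evaluation may need tens of integrations.

Parameter vectors follow the canonical order in ``model.BASE_PARAMS`` /
``model.DUP_PARAMS``; state vectors follow ``model.BASE_SPECIES`` /
``model.DUP_SPECIES``.
"""

import numpy as np
from numba import njit

# Canonical parameter indices (base model, 31 free parameters).
(
    I_KE_MYC, I_D_MYC, I_K_CDM, I_K_CDS, I_D_CD,
    I_K_E2FM, I_K_AUTO, I_K_TL, I_D_E2FM, I_D_E2FP,
    I_K_ADEG, I_K_RB, I_D_RB, I_K_PHD, I_KM_PHD,
    I_K_PHE, I_KM_PHE, I_K_DEPH, I_D_RP, I_K_CE,
    I_D_CE, I_K_A, I_D_A, I_K_X, I_K_XM,
    I_D_X, I_K_S, I_K_M, I_K_P, I_K_RBH, I_K_XH,
) = range(31)

# Duplicated-E2F extension appends five parameters.
(I_K_E2FM2, I_K_AUTO2, I_K_TL2, I_D_E2FM2, I_D_E2FP2) = range(31, 36)

NS_BASE = 9
NS_DUP = 11


@njit(cache=True, fastmath=False)
def _base_step(y, off, dy, p, sig, ke_const):
    """Writes d/dt of one base-model replica at state offset ``off``."""
    M = y[off + 0]
    D = y[off + 1]
    m = y[off + 2]
    P = y[off + 3]
    Rb = y[off + 4]
    Rp = y[off + 5]
    E = y[off + 6]
    A = y[off + 7]
    X = y[off + 8]

    myc_frac = M / (p[I_K_M] + M)
    rb_gate = p[I_K_RBH] / (p[I_K_RBH] + Rb)
    x_gate = p[I_K_XH] / (p[I_K_XH] + X)
    p_frac = P / (p[I_K_P] + P)
    phD = p[I_K_PHD] * D * Rb / (p[I_KM_PHD] + Rb)
    phE = p[I_K_PHE] * E * Rb / (p[I_KM_PHE] + Rb)
    M2 = M * M

    dy[off + 0] = p[I_KE_MYC] * sig + ke_const - p[I_D_MYC] * M
    dy[off + 1] = p[I_K_CDM] * myc_frac + p[I_K_CDS] * sig - p[I_D_CD] * D
    dy[off + 2] = (p[I_K_E2FM] * myc_frac + p[I_K_AUTO] * p_frac) * rb_gate * x_gate \
        - p[I_D_E2FM] * m
    dy[off + 3] = p[I_K_TL] * m - p[I_D_E2FP] * P - p[I_K_ADEG] * A * P
    dy[off + 4] = p[I_K_RB] - p[I_D_RB] * Rb - phD - phE + p[I_K_DEPH] * Rp
    dy[off + 5] = phD + phE - p[I_K_DEPH] * Rp - p[I_D_RP] * Rp
    dy[off + 6] = p[I_K_CE] * p_frac - p[I_D_CE] * E
    dy[off + 7] = p[I_K_A] * p_frac - p[I_D_A] * A
    dy[off + 8] = p[I_K_X] * M2 / (p[I_K_XM] * p[I_K_XM] + M2) - p[I_D_X] * X


@njit(cache=True, fastmath=False)
def _dup_step(y, off, dy, p, sig, ke_const):
    """One duplicated-E2F replica: E2F' shares activity with E2F.

    Everywhere E2F protein acts as a regulator (autoactivation, CycE and
    CycA/SKP2 induction) the total P + P' enters; the NFB-driven
    degradation acts on both copies.
    """
    M = y[off + 0]
    D = y[off + 1]
    m = y[off + 2]
    P = y[off + 3]
    Rb = y[off + 4]
    Rp = y[off + 5]
    E = y[off + 6]
    A = y[off + 7]
    X = y[off + 8]
    m2 = y[off + 9]
    P2 = y[off + 10]

    Pt = P + P2
    myc_frac = M / (p[I_K_M] + M)
    rb_gate = p[I_K_RBH] / (p[I_K_RBH] + Rb)
    x_gate = p[I_K_XH] / (p[I_K_XH] + X)
    p_frac = Pt / (p[I_K_P] + Pt)
    phD = p[I_K_PHD] * D * Rb / (p[I_KM_PHD] + Rb)
    phE = p[I_K_PHE] * E * Rb / (p[I_KM_PHE] + Rb)
    M2sq = M * M

    dy[off + 0] = p[I_KE_MYC] * sig + ke_const - p[I_D_MYC] * M
    dy[off + 1] = p[I_K_CDM] * myc_frac + p[I_K_CDS] * sig - p[I_D_CD] * D
    dy[off + 2] = (p[I_K_E2FM] * myc_frac + p[I_K_AUTO] * p_frac) * rb_gate * x_gate \
        - p[I_D_E2FM] * m
    dy[off + 3] = p[I_K_TL] * m - p[I_D_E2FP] * P - p[I_K_ADEG] * A * P
    dy[off + 4] = p[I_K_RB] - p[I_D_RB] * Rb - phD - phE + p[I_K_DEPH] * Rp
    dy[off + 5] = phD + phE - p[I_K_DEPH] * Rp - p[I_D_RP] * Rp
    dy[off + 6] = p[I_K_CE] * p_frac - p[I_D_CE] * E
    dy[off + 7] = p[I_K_A] * p_frac - p[I_D_A] * A
    dy[off + 8] = p[I_K_X] * M2sq / (p[I_K_XM] * p[I_K_XM] + M2sq) - p[I_D_X] * X
    dy[off + 9] = (p[I_K_E2FM2] * myc_frac + p[I_K_AUTO2] * p_frac) * rb_gate * x_gate \
        - p[I_D_E2FM2] * m2
    dy[off + 10] = p[I_K_TL2] * m2 - p[I_D_E2FP2] * P2 - p[I_K_ADEG] * A * P2


@njit(cache=True)
def rhs_base(y, t, p, sig, ke_const):
    dy = np.empty(NS_BASE)
    _base_step(y, 0, dy, p, sig, ke_const)
    return dy


@njit(cache=True)
def rhs_dup(y, t, p, sig, ke_const):
    dy = np.empty(NS_DUP)
    _dup_step(y, 0, dy, p, sig, ke_const)
    return dy


@njit(cache=True)
def rhs_base_batch(y, t, p, sigs, kes):
    """Independent base replicas stacked into one state vector.

    Used to integrate a whole dose grid in a single LSODA call; the
    Jacobian is block diagonal, so the driver is told it is banded with
    half-bandwidth NS_BASE - 1.
    """
    n = sigs.shape[0]
    dy = np.empty(n * NS_BASE)
    for i in range(n):
        _base_step(y, i * NS_BASE, dy, p, sigs[i], kes[i])
    return dy


@njit(cache=True)
def rhs_dup_batch(y, t, p, sigs, kes):
    n = sigs.shape[0]
    dy = np.empty(n * NS_DUP)
    for i in range(n):
        _dup_step(y, i * NS_DUP, dy, p, sigs[i], kes[i])
    return dy
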