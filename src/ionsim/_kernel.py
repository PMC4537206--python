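"""Numba-compiled right-hand side and fixed-step RK4 loop.

Numerically identical to the reference formulation in ``ionsim.core``
(held together by tests); exists because parameter sweeps integrate
10^7-10^8 steps.  The packed parameter vector layout is defined in
``ionsim.parameters``.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .parameters import (
    IDX, IDX_ASS, IDX_BETA_OVERRIDE, IDX_CLFIXED, IDX_CLI_FIX, IDX_CLO_FIX,
    IDX_DILUTION, IDX_DYNVOL, IDX_FREEZE_SLOW, IDX_GATE_DIFF, IDX_GATE_GLIA,
    IDX_IRAND, IDX_RATEEQ, IDX_RTOT, IDX_VOL0,
)

# scalar slots read inside the jitted code
_iC = IDX["C"]; _igNa = IDX["gNa_bar"]; _igK = IDX["gK_bar"]
_igKL = IDX["gKL_bar"]; _igNaL = IDX["gNaL_bar"]; _igClL = IDX["gClL_bar"]
_iphi = IDX["phi"]; _irho = IDX["rho"]; _iBg = IDX["B_glia"]
_iepsK = IDX["eps_K"]; _iepsO = IDX["eps_O"]; _iO2inf = IDX["O2_inf"]
_iKoinf = IDX["K_o_inf"]; _ialpha = IDX["alpha_O2"]; _irKCC = IDX["rho_KCC"]
_itau = IDX["tau"]; _itauv = IDX["tau_v"]; _iCao = IDX["Ca_o"]
_iCai = IDX["Ca_i"]; _iAi = IDX["A_i"]; _iAo = IDX["A_o"]
_inernst = IDX["nernst_scale"]; _iF = IDX["F"]
_ipNaMid = IDX["pump_Na_mid"]; _ipNaSlope = IDX["pump_Na_slope"]
_ipKHalf = IDX["pump_K_half"]; _ipKHill = IDX["pump_K_hill"]

FOUR_PI = 4.0 * math.pi


@njit(cache=True, fastmath=False)
def rhs(y, p, irand, dy):
    V = y[0]; n = y[1]; h = y[2]; Ko = y[3]; Nai = y[4]; Cli = y[5]
    O2 = y[6]; Vol = y[7]

    # geometry (dynamic when volume is a variable)
    rt = p[IDX_RTOT]
    r = (3.0 * Vol / FOUR_PI) ** (1.0 / 3.0)
    A = FOUR_PI * r * r
    Vol_o = FOUR_PI / 3.0 * rt**3 - Vol
    beta = Vol / Vol_o
    if p[IDX_BETA_OVERRIDE] == p[IDX_BETA_OVERRIDE]:  # not nan
        beta = p[IDX_BETA_OVERRIDE]
    gamma = A / (p[_iF] * Vol)

    dynvol = p[IDX_DYNVOL] > 0.5
    if dynvol:
        sc = p[IDX_ASS] / A
    else:
        sc = 1.0
    gNa = p[_igNa] * sc; gK = p[_igK] * sc; gKL = p[_igKL] * sc
    gNaL = p[_igNaL] * sc; gClL = p[_igClL] * sc

    rate_eq = p[IDX_RATEEQ] > 0.5
    if rate_eq:
        Ki = y[8]; Nao = y[9]; Clo = y[10]
    else:
        Ki = 140.0 + (18.0 - Nai)
        Nao = 144.0 - beta * (Nai - 18.0)
        Clo = Ko + Nao + 2.0 * p[_iCao] - p[_iAo]
    cl_fixed = p[IDX_CLFIXED] > 0.5
    if cl_fixed:
        Cli = p[IDX_CLI_FIX]
        Clo = p[IDX_CLO_FIX]

    ns = p[_inernst]
    VK = ns * math.log(Ko / Ki)
    VNa = ns * math.log(Nao / Nai)
    VCl = ns * math.log(Cli / Clo)

    # gating rates (removable singularities filled analytically)
    x = V + 30.0
    if abs(x) < 1e-7:
        am = 1.0 + 0.05 * x
    else:
        am = 0.1 * x / (1.0 - math.exp(-0.1 * x))
    bm = 4.0 * math.exp(-(V + 55.0) / 18.0)
    xn = V + 34.0
    if abs(xn) < 1e-7:
        an = 0.1 + 0.005 * xn
    else:
        an = 0.01 * xn / (1.0 - math.exp(-0.1 * xn))
    bn = 0.125 * math.exp(-(V + 44.0) / 80.0)
    ah = 0.07 * math.exp(-(V + 44.0) / 20.0)
    bh = 1.0 / (1.0 + math.exp(-0.1 * (V + 14.0)))
    m = am / (am + bm)

    INa = -gNa * m**3 * h * (V - VNa)
    IK = -gK * n**4 * (V - VK)
    IKL = -gKL * (V - VK)
    INaL = -gNaL * (V - VNa)
    IClL = -gClL * (V - VCl)

    FO2 = 1.0 / (1.0 + math.exp((16.0 - O2) / 4.0))
    sNa = 1.0 / (1.0 + math.exp((p[_ipNaMid] - Nai) / p[_ipNaSlope]))
    sK = (Ko / (Ko + p[_ipKHalf])) ** p[_ipKHill]
    Jp = FO2 * p[_irho] * sNa * sK          # mM/s
    Ip = Jp / gamma                          # uA/cm^2

    if p[IDX_GATE_DIFF] > 0.5:
        Idiff = FO2 * p[_iepsK] * (Ko - p[_iKoinf])
    else:
        Idiff = p[_iepsK] * (Ko - p[_iKoinf])
    if p[IDX_GATE_GLIA] > 0.5:
        Iglia = FO2 * p[_iBg] / (1.0 + math.exp((18.0 - Ko) / 2.5))
    else:
        Iglia = p[_iBg] / (1.0 + math.exp((18.0 - Ko) / 2.5))
    IKCC = p[_irKCC] * math.log(Ki * Cli / (Ko * Clo))

    JK_out = -(IK + IKL)
    JCl_in = -IClL

    tau = p[_itau]
    dy[0] = (INa + IK + IKL + INaL + IClL - Ip + irand) / p[_iC]
    dy[1] = p[_iphi] * (an * (1.0 - n) - bn * n)
    dy[2] = p[_iphi] * (ah * (1.0 - h) - bh * h)
    if p[IDX_FREEZE_SLOW] > 0.5:
        for j in range(3, 11):
            dy[j] = 0.0
        return

    dy[3] = (gamma * beta * JK_out - 2.0 * beta * Jp
             - Idiff - Iglia + IKCC) / tau
    dy[4] = (gamma * (INa + INaL) - 3.0 * Jp) / tau
    if cl_fixed:
        dy[5] = 0.0
    else:
        dy[5] = (gamma * JCl_in - IKCC / beta) / tau
    o2_cons = p[_ialpha] * Jp if O2 > 0.0 else 0.0   # empty pool: nothing to consume
    dy[6] = (-o2_cons + p[_iepsO] * (p[_iO2inf] - O2)) / tau

    if dynvol:
        pii = Nai + Cli + Ki + p[_iAi] + p[_iCai]
        pio = Nao + Clo + Ko + p[_iAo] + p[_iCao]
        Volhat = p[IDX_VOL0] * (1.1029 - 0.1029 * math.exp((pio - pii) / 20.0))
        dy[7] = (Volhat - Vol) / (p[_itauv] * tau)
        if p[IDX_DILUTION] > 0.5:
            dvol = dy[7]
            dy[3] += dvol * Ko / Vol_o
            dy[4] += -dvol * Nai / Vol
            if not cl_fixed:
                dy[5] += -dvol * Cli / Vol
    else:
        dy[7] = 0.0

    if rate_eq:
        dy[8] = (-gamma * JK_out + 2.0 * Jp - IKCC / beta) / tau
        dy[9] = -beta * (gamma * (INa + INaL) - 3.0 * Jp) / tau
        dy[10] = (-gamma * beta * JCl_in + IKCC) / tau
    else:
        dy[8] = 0.0
        dy[9] = 0.0
        dy[10] = 0.0


@njit(cache=True)
def rk4_integrate(y0, p, dt, n_steps, stride, irand_sd, seed):
    """Classical RK4 with fixed step ``dt`` (ms).

    Records every ``stride`` steps (including the initial state).  The
    random background current, when enabled, is redrawn once per step and
    held constant across the four stage evaluations.  Returns
    (records, status): status 0 on success, 1 if a non-finite state was
    produced (integration stops at the last valid record).  Also
    returns the exact final state vector.
    """
    nrec = n_steps // stride + 1
    out = np.empty((nrec, 11))
    y = y0.copy()
    k1 = np.empty(11); k2 = np.empty(11); k3 = np.empty(11); k4 = np.empty(11)
    yt = np.empty(11)
    out[0] = y
    irec = 1
    if irand_sd > 0.0:
        np.random.seed(seed)
    for i in range(n_steps):
        irand = irand_sd * np.random.standard_normal() if irand_sd > 0.0 else 0.0
        rhs(y, p, irand, k1)
        for j in range(11):
            yt[j] = y[j] + 0.5 * dt * k1[j]
        rhs(yt, p, irand, k2)
        for j in range(11):
            yt[j] = y[j] + 0.5 * dt * k2[j]
        rhs(yt, p, irand, k3)
        for j in range(11):
            yt[j] = y[j] + dt * k3[j]
        rhs(yt, p, irand, k4)
        ok = True
        for j in range(11):
            y[j] = y[j] + dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
            if not math.isfinite(y[j]):
                ok = False
        if not ok:
            return out[:irec], y, 1
        if (i + 1) % stride == 0 and irec < nrec:
            out[irec] = y
            irec += 1
    return out[:irec], y, 0
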