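"""Model quantities and the right-hand side of the coupled ODE system.

This module is the readable reference formulation; the simulation engine
uses a numerically identical compiled kernel (``ionsim._kernel``), and the
two are held together by tests.  All functions accept scalars or numpy
arrays.

Sign conventions: channel currents are written inward-positive in the
membrane equation (I_Na = -gNa m^3 h (V - V_Na), summed with ``+`` signs
into C dV/dt together with ``-I_pump``).  The ion-concentration equations
use the corresponding ion fluxes: the outward K+ channel flux raises
[K]o, the Na+ channel influx raises [Na]i, and the Cl- influx (outward
conventional current) raises [Cl]i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Geometry, geometry_from_volume
from .parameters import ModelParameters, VariantFlags

OSMOTIC_CEILING = 1.1029   # maximal relative swelling
OSMOTIC_SPAN = 0.1029
OSMOTIC_SCALE = 20.0       # mM


class DomainError(ValueError):
    """Raised when an input leaves the physical domain of an operation."""


@dataclass
class FullState:
    """The dynamical variables at one instant.

    ``K_i``, ``Na_o``, ``Cl_o`` are carried only in the rate-equation
    variant; under conservation closure they are derived quantities.
    """

    V: float
    n: float
    h: float
    K_o: float
    Na_i: float
    Cl_i: float
    O2: float
    Vol: float
    K_i: float | None = None
    Na_o: float | None = None
    Cl_o: float | None = None

    def to_vector(self) -> np.ndarray:
        return np.array([
            self.V, self.n, self.h, self.K_o, self.Na_i, self.Cl_i,
            self.O2, self.Vol,
            self.K_i if self.K_i is not None else 0.0,
            self.Na_o if self.Na_o is not None else 0.0,
            self.Cl_o if self.Cl_o is not None else 0.0,
        ])

    @classmethod
    def from_vector(cls, y, rate_equations: bool = False) -> "FullState":
        s = cls(*[float(v) for v in y[:8]])
        if rate_equations:
            s.K_i, s.Na_o, s.Cl_o = float(y[8]), float(y[9]), float(y[10])
        return s


# ---------------------------------------------------------------------------
# gating

def gating_rates(V):
    """The six Hodgkin-Huxley opening/closing rates (ms^-1, before the
    phi scaling).  The removable singularities of alpha_m (V = -30) and
    alpha_n (V = -34) are filled with their analytic limits."""
    V = np.asarray(V, dtype=float)
    x = V + 30.0
    with np.errstate(over="ignore"):
        am = np.where(np.abs(x) < 1e-7, 1.0 + 0.05 * x,
                      0.1 * x / (1.0 - np.exp(-0.1 * np.where(np.abs(x) < 1e-7, 1.0, x))))
        bm = 4.0 * np.exp(-(V + 55.0) / 18.0)
        xn = V + 34.0
        an = np.where(np.abs(xn) < 1e-7, 0.1 + 0.005 * xn,
                      0.01 * xn / (1.0 - np.exp(-0.1 * np.where(np.abs(xn) < 1e-7, 1.0, xn))))
        bn = 0.125 * np.exp(-(V + 44.0) / 80.0)
        ah = 0.07 * np.exp(-(V + 44.0) / 20.0)
        bh = 1.0 / (1.0 + np.exp(-0.1 * (V + 14.0)))
    return am, bm, an, bn, ah, bh


def m_infinity(V):
    """Instantaneous steady state of the Na+ activation gate."""
    am, bm, *_ = gating_rates(V)
    return am / (am + bm)


def n_infinity(V):
    _, _, an, bn, _, _ = gating_rates(V)
    return an / (an + bn)


def h_infinity(V):
    *_, ah, bh = gating_rates(V)
    return ah / (ah + bh)


# ---------------------------------------------------------------------------
# fluxes and currents

def nernst_potentials(K_o, K_i, Na_o, Na_i, Cl_o, Cl_i, scale: float = 26.64):
    """Reversal potentials (mV); note the inverted ratio for the anion."""
    for name, c in (("K_o", K_o), ("K_i", K_i), ("Na_o", Na_o),
                    ("Na_i", Na_i), ("Cl_o", Cl_o), ("Cl_i", Cl_i)):
        if np.any(np.asarray(c) <= 0):
            raise DomainError(f"nonpositive concentration for {name}")
    v_k = scale * np.log(np.asarray(K_o) / K_i)
    v_na = scale * np.log(np.asarray(Na_o) / Na_i)
    v_cl = scale * np.log(np.asarray(Cl_i) / Cl_o)
    return v_k, v_na, v_cl


def oxygen_gate(O2):
    """Sigmoidal availability factor for pump, glia, and diffusion;
    midpoint 16 mg/L, width 4 mg/L."""
    return 1.0 / (1.0 + np.exp((16.0 - np.asarray(O2, dtype=float)) / 4.0))


def pump_rate(Na_i, K_o, F_O2, params: ModelParameters):
    """Na/K-ATPase transport flux (mM/s): sigmoidal in Na_i, Hill in K_o,
    gated by oxygen.  Bounded by params.rho."""
    s_na = 1.0 / (1.0 + np.exp((params.pump_Na_mid - np.asarray(Na_i)) /
                               params.pump_Na_slope))
    s_k = (np.asarray(K_o) / (np.asarray(K_o) + params.pump_K_half)) \
        ** params.pump_K_hill
    return F_O2 * params.rho * s_na * s_k


def pump_current(Na_i, K_o, F_O2, params: ModelParameters,
                 gamma: float):
    """Electrogenic pump current (uA/cm^2): the transport flux converted
    through gamma = A/(F*Vol_i)."""
    return pump_rate(Na_i, K_o, F_O2, params) / gamma


def glial_uptake(K_o, F_O2, B_glia: float):
    """Glial K+ buffering flux (mM/s), sigmoidal in K_o (midpoint 18 mM,
    width 2.5 mM), gated by oxygen."""
    return F_O2 * B_glia / (1.0 + np.exp((18.0 - np.asarray(K_o)) / 2.5))


def reservoir_diffusion(K_o, F_O2, eps_K: float, K_o_inf: float,
                        gated: bool = True):
    """K+ exchange with the distant reservoir (mM/s), positive when the
    extracellular space loses K+."""
    gate = F_O2 if gated else 1.0
    return gate * eps_K * (np.asarray(K_o) - K_o_inf)


def kcc_flux(K_i, Cl_i, K_o, Cl_o, rho_KCC: float):
    """KCC2 cotransport flux (mM/s); zero at the thermodynamic
    equilibrium [K]i[Cl]i = [K]o[Cl]o, positive for K+/Cl- extrusion."""
    for name, c in (("K_i", K_i), ("Cl_i", Cl_i), ("K_o", K_o),
                    ("Cl_o", Cl_o)):
        if np.any(np.asarray(c) <= 0):
            raise DomainError(f"nonpositive concentration for {name}")
    return rho_KCC * np.log(np.asarray(K_i) * Cl_i / (np.asarray(K_o) * Cl_o))


class StateValidityError(ValueError):
    pass


def conserved_concentrations(Na_i, K_o, beta, params: ModelParameters,
                             strict: bool = True):
    """Close [K]i, [Na]o, [Cl]o by ion/charge conservation.

    [K]i = 140 + (18 - [Na]i); [Na]o = 144 - beta([Na]i - 18);
    [Cl]o = [K]o + [Na]o + 2[Ca]o - [A]o (the anion term restores the
    resting charge balance at [Cl]o = 132 mM).
    """
    k_i = params.K_i_rest + (params.Na_i_rest - np.asarray(Na_i))
    na_o = params.Na_o_rest - beta * (np.asarray(Na_i) - params.Na_i_rest)
    cl_o = np.asarray(K_o) + na_o + 2.0 * params.Ca_o - params.A_o
    if strict and (np.any(k_i <= 0) or np.any(na_o <= 0)
                   or np.any(cl_o <= 0)):
        raise StateValidityError(
            "conservation relations produced a nonpositive concentration "
            f"(K_i={np.min(k_i):.3g}, Na_o={np.min(na_o):.3g}, "
            f"Cl_o={np.min(cl_o):.3g})")
    return k_i, na_o, cl_o


def membrane_currents(V, n, h, v_k, v_na, v_cl, gNa, gK, gKL, gNaL, gClL):
    """Channel currents (uA/cm^2), inward-positive: each vanishes at its
    reversal potential."""
    m = m_infinity(V)
    i_na = -gNa * m**3 * h * (V - v_na)
    i_k = -gK * np.asarray(n)**4 * (V - v_k)
    i_kl = -gKL * (np.asarray(V) - v_k)
    i_nal = -gNaL * (np.asarray(V) - v_na)
    i_cll = -gClL * (np.asarray(V) - v_cl)
    return i_na, i_k, i_kl, i_nal, i_cll


def osmolarities(state_concs, params: ModelParameters):
    """(pi_i, pi_o): total osmolarities including the impermeant anions
    and fixed Ca2+ on each side."""
    na_i, cl_i, k_i, k_o, na_o, cl_o = state_concs
    pi_i = na_i + cl_i + k_i + params.A_i + params.Ca_i
    pi_o = na_o + cl_o + k_o + params.A_o + params.Ca_o
    return pi_i, pi_o


def osmotic_target_volume(pi_i, pi_o, vol_initial):
    """Equilibrium volume for an osmolarity difference: saturating
    exponential with a +10.29 % swelling ceiling, equal to vol_initial
    at osmotic balance, decreasing in (pi_o - pi_i)."""
    factor = OSMOTIC_CEILING - OSMOTIC_SPAN * np.exp(
        (np.asarray(pi_o) - pi_i) / OSMOTIC_SCALE)
    return vol_initial * factor


def scale_conductances(a_ins, a_ss, params: ModelParameters):
    """Rescale conductance densities so the total conductance of the
    whole cell is invariant under area changes: g = g_bar * (A_ss/A_ins)."""
    s = a_ss / a_ins
    return (params.gNa_bar * s, params.gK_bar * s, params.gKL_bar * s,
            params.gNaL_bar * s, params.gClL_bar * s)


# ---------------------------------------------------------------------------
# full right-hand side (reference implementation)

def full_rhs(state: FullState, params: ModelParameters, flags: VariantFlags,
             geometry: Geometry, irand: float = 0.0) -> np.ndarray:
    """Time derivatives (per ms) of the 11-slot state vector.

    Dependency order: geometry -> closures -> Nernst -> oxygen gate ->
    currents/fluxes -> osmotic target.  Under conservation closure the
    K_i/Na_o/Cl_o slots have zero derivative; in the rate-equation
    variant they obey their own ODEs.
    """
    p, f = params, flags
    if f.dynamic_volume:
        geo = geometry_from_volume(state.Vol, geometry.r_tot, geometry.A_ss)
        gNa, gK, gKL, gNaL, gClL = scale_conductances(geo.A, geo.A_ss, p)
    else:
        geo = geometry
        gNa, gK, gKL, gNaL, gClL = (p.gNa_bar, p.gK_bar, p.gKL_bar,
                                    p.gNaL_bar, p.gClL_bar)
    beta, gamma = geo.beta, geo.gamma

    rate_eq = f.concentration_mode == "rate_equations"
    if rate_eq:
        k_i, na_o, cl_o = state.K_i, state.Na_o, state.Cl_o
    else:
        k_i, na_o, cl_o = conserved_concentrations(
            state.Na_i, state.K_o, beta, p)
    cl_i = state.Cl_i
    if f.chloride_mode == "fixed":
        cl_i, cl_o = f.cl_i_fixed, f.cl_o_fixed

    v_k, v_na, v_cl = nernst_potentials(
        state.K_o, k_i, na_o, state.Na_i, cl_o, cl_i, p.nernst_scale)
    f_o2 = oxygen_gate(state.O2)
    i_na, i_k, i_kl, i_nal, i_cll = membrane_currents(
        state.V, state.n, state.h, v_k, v_na, v_cl, gNa, gK, gKL, gNaL, gClL)
    j_pump = pump_rate(state.Na_i, state.K_o, f_o2, p)
    i_pump = j_pump / gamma
    i_diff = reservoir_diffusion(state.K_o, f_o2, p.eps_K, p.K_o_inf,
                                 gated=f.o2_gate_diffusion)
    i_glia = glial_uptake(state.K_o, f_o2 if f.o2_gate_glia else 1.0,
                          p.B_glia)
    i_kcc = kcc_flux(k_i, cl_i, state.K_o, cl_o, p.rho_KCC)

    j_k_out = -(i_k + i_kl)      # outward K+ channel flux (uA/cm^2)
    j_cl_in = -i_cll             # Cl- influx (uA/cm^2)

    dy = np.zeros(11)
    am, bm, an, bn, ah, bh = gating_rates(state.V)
    dy[0] = (i_na + i_k + i_kl + i_nal + i_cll - i_pump + irand) / p.C
    dy[1] = p.phi * (an * (1.0 - state.n) - bn * state.n)
    dy[2] = p.phi * (ah * (1.0 - state.h) - bh * state.h)
    dy[3] = (gamma * beta * j_k_out - 2.0 * beta * j_pump
             - i_diff - i_glia + i_kcc) / p.tau
    dy[4] = (gamma * (i_na + i_nal) - 3.0 * j_pump) / p.tau
    if f.chloride_mode == "dynamic":
        dy[5] = (gamma * j_cl_in - i_kcc / beta) / p.tau
    o2_cons = p.alpha_O2 * j_pump if state.O2 > 0 else 0.0
    dy[6] = (-o2_cons + p.eps_O * (p.O2_inf - state.O2)) / p.tau

    if f.dynamic_volume:
        pi_i, pi_o = osmolarities(
            (state.Na_i, cl_i, k_i, state.K_o, na_o, cl_o), p)
        vol_hat = osmotic_target_volume(pi_i, pi_o, _vol0(geometry))
        dy[7] = (vol_hat - state.Vol) / (p.tau_v * p.tau)
        if f.dilution_flux:
            dvol = dy[7]
            dy[3] += dvol * state.K_o / geo.Vol_o        # -dVol_o/dt * Ko/Vol_o
            dy[4] += -dvol * state.Na_i / geo.Vol_i
            if f.chloride_mode == "dynamic":
                dy[5] += -dvol * cl_i / geo.Vol_i

    if rate_eq:
        # mirror images of the d[K]o, d[Na]i, d[Cl]i balances scaled by
        # the volume ratio; see the methods note for the Cl_o KCC term
        dy[8] = (-gamma * j_k_out + 2.0 * j_pump - i_kcc / beta) / p.tau
        dy[9] = -beta * (gamma * (i_na + i_nal) - 3.0 * j_pump) / p.tau
        dy[10] = (-gamma * beta * j_cl_in + i_kcc) / p.tau

    if not np.all(np.isfinite(dy)):
        bad = [name for name, v in zip(
            ("dV", "dn", "dh", "dK_o", "dNa_i", "dCl_i", "dO2", "dVol",
             "dK_i", "dNa_o", "dCl_o"), dy) if not np.isfinite(v)]
        raise FloatingPointError(
            f"non-finite derivative in {', '.join(bad)}")
    return dy


def _vol0(geometry: Geometry) -> float:
    """Osmotic reference volume: the volume at the reference area A_ss."""
    import math
    r_ss = math.sqrt(geometry.A_ss / (4.0 * math.pi))
    return 4.0 * math.pi / 3.0 * r_ss**3


def derived_quantities(state: FullState, params: ModelParameters,
                       flags: VariantFlags, geometry: Geometry) -> dict:
    """The auxiliary quantities of the model at one state."""
    p, f = params, flags
    if f.dynamic_volume:
        geo = geometry_from_volume(state.Vol, geometry.r_tot, geometry.A_ss)
    else:
        geo = geometry
    if f.concentration_mode == "rate_equations":
        k_i, na_o, cl_o = state.K_i, state.Na_o, state.Cl_o
    else:
        k_i, na_o, cl_o = conserved_concentrations(
            state.Na_i, state.K_o, geo.beta, p)
    cl_i = state.Cl_i
    if f.chloride_mode == "fixed":
        cl_i, cl_o = f.cl_i_fixed, f.cl_o_fixed
    v_k, v_na, v_cl = nernst_potentials(
        state.K_o, k_i, na_o, state.Na_i, cl_o, cl_i, p.nernst_scale)
    f_o2 = oxygen_gate(state.O2)
    j_pump = pump_rate(state.Na_i, state.K_o, f_o2, p)
    pi_i, pi_o = osmolarities(
        (state.Na_i, cl_i, k_i, state.K_o, na_o, cl_o), p)
    return dict(K_i=k_i, Na_o=na_o, Cl_o=cl_o, V_K=v_k, V_Na=v_na,
                V_Cl=v_cl, F_O2=f_o2, J_pump=j_pump,
                I_pump=j_pump / geo.gamma, pi_i=pi_i, pi_o=pi_o,
                r_in=geo.r_in, beta=geo.beta, gamma=geo.gamma)
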