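"""Model parameters, variant flags, and their packed numeric representation.

The model couples Hodgkin-Huxley membrane dynamics to extracellular K+,
intracellular Na+ and Cl-, local O2, and osmotic cell-volume dynamics for a
spherical neuron of radius ``r_in`` inside a fixed shell of radius
``r_tot`` = 5 um.  Defaults are the operating point of the unified
seizure / spreading-depression / anoxic-depolarization single-neuron model.

Units
-----
Conductance densities mS/cm^2, currents uA/cm^2, transport fluxes mM/s,
concentrations mM, O2 mg/L, volumes cm^3, areas cm^2, potentials mV.
The integrator steps in ms; the concentration and O2 equations carry the
explicit 1/tau (tau = 1000 ms/s) conversion.  ``tau_v`` is in seconds:
volume relaxation competes with the 30-100 s seizure cycle, which is what
makes the seizure-to-SD transition sensitive to it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

FARADAY = 96485.0  # C/mol
NERNST_SCALE = 26.64  # mV


def eps_from_fick(D: float, dx: float) -> float:
    """Fick's-law rate constant 2*D/dx^2 (s^-1) for exchange with a
    reservoir a distance ``dx`` (cm) away, given diffusivity ``D`` (cm^2/s)."""
    return 2.0 * D / dx**2


@dataclass(frozen=True)
class ModelParameters:
    """All constants of the model; immutable per run.

    The Na/K-ATPase is parameterized as a transport flux (mM/s)

        J_pump = F(O2) * rho / (1 + exp((pump_Na_mid - Na_i)/pump_Na_slope))
                 * (K_o / (K_o + pump_K_half))**pump_K_hill

    with a Hill-type K+ dependence (half-saturation ``pump_K_half``); its
    electrogenic current in the membrane equation is J_pump/gamma where
    gamma = A/(F*Vol_i) converts uA/cm^2 to mM/s.
    """

    C: float = 1.0                 # uF/cm^2
    gNa_bar: float = 100.0         # mS/cm^2
    gK_bar: float = 40.0           # mS/cm^2
    gKL_bar: float = 0.05          # mS/cm^2
    gNaL_bar: float = 0.02        # mS/cm^2
    gClL_bar: float = 0.05         # mS/cm^2
    phi: float = 3.0               # gating rate scale
    rho: float = 1.25              # max pump transport strength, mM/s
    B_glia: float = 5.0            # max glial uptake, mM/s
    eps_K: float = 0.33            # s^-1, K+ exchange with the reservoir
    D_K: float = 250e-6            # cm^2/s (Fick helper input, informational)
    dx: float = 20e-4              # cm, neuron-capillary distance
    eps_O: float = 0.34            # s^-1
    O2_inf: float = 30.0           # mg/L
    K_o_inf: float = 4.0           # mM
    alpha_O2: float = 6.0          # (mg/L/s) per (mM/s)
    rho_KCC: float = 0.5           # mM/s
    tau: float = 1000.0            # ms per s
    tau_v: float = 50.0            # s, volume relaxation time
    F: float = FARADAY             # C/mol
    Ca_o: float = 1.0              # mM
    Ca_i: float = 1e-4             # mM (100 nM)
    A_i: float = 132.1             # mM, impermeant intracellular anions
    A_o: float = 18.0              # mM, impermeant extracellular anions
    Na_i_rest: float = 18.0        # mM
    K_i_rest: float = 140.0        # mM
    Na_o_rest: float = 144.0       # mM
    nernst_scale: float = NERNST_SCALE  # mV
    pump_Na_mid: float = 25.0      # mM
    pump_Na_slope: float = 3.0     # mM
    pump_K_half: float = 3.5       # mM
    pump_K_hill: float = 2.0

    def __post_init__(self) -> None:
        for name in ("C", "gNa_bar", "gK_bar", "gKL_bar", "gNaL_bar",
                     "gClL_bar", "phi", "rho", "B_glia", "eps_K", "eps_O",
                     "tau", "tau_v", "F"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name!r} must be strictly positive")

    def replace(self, **kw) -> "ModelParameters":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class VariantFlags:
    """Configuration variants.

    dynamic_volume
        When off, Vol stays at its initial value and conductances are
        not rescaled (volume acts as a bifurcation parameter).
    concentration_mode
        'conservation' closes [K]i, [Na]o, [Cl]o algebraically;
        'rate_equations' integrates them as three extra ODEs.
    chloride_mode
        'dynamic' integrates [Cl]i; 'fixed' pins [Cl]i = 8 mM and
        [Cl]o = 140 mM.
    o2_gate_diffusion / o2_gate_glia
        Whether reservoir K+ diffusion / glial uptake are gated by the
        local-O2 sigmoid; ungated diffusion is the "normal diffusion"
        variant that prevents anoxic depolarization.
    dilution_flux
        Off by default: volume changes do not renormalize concentrations.
    irand_sd
        Amplitude (uA/cm^2) of a zero-mean Gaussian background current,
        redrawn each integrator step; 0 disables it.
    """

    dynamic_volume: bool = False
    concentration_mode: str = "conservation"
    chloride_mode: str = "dynamic"
    cl_i_fixed: float = 8.0
    cl_o_fixed: float = 140.0
    o2_gate_diffusion: bool = True
    o2_gate_glia: bool = True
    dilution_flux: bool = False
    irand_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.concentration_mode not in ("conservation", "rate_equations"):
            raise ValueError(
                f"unknown concentration_mode {self.concentration_mode!r}")
        if self.chloride_mode not in ("dynamic", "fixed"):
            raise ValueError(f"unknown chloride_mode {self.chloride_mode!r}")

    def replace(self, **kw) -> "VariantFlags":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# packed parameter vector for the compiled kernel

_PACK_FIELDS = [
    "C", "gNa_bar", "gK_bar", "gKL_bar", "gNaL_bar", "gClL_bar", "phi",
    "rho", "B_glia", "eps_K", "eps_O", "O2_inf", "K_o_inf", "alpha_O2",
    "rho_KCC", "tau", "tau_v", "Ca_o", "Ca_i", "A_i", "A_o",
    "nernst_scale", "F", "pump_Na_mid", "pump_Na_slope", "pump_K_half",
    "pump_K_hill",
]
IDX = {name: i for i, name in enumerate(_PACK_FIELDS)}
_N = len(_PACK_FIELDS)
IDX_RTOT = _N + 0          # cm
IDX_VOL0 = _N + 1          # cm^3, osmotic reference volume
IDX_ASS = _N + 2           # cm^2, reference area for conductance scaling
IDX_DYNVOL = _N + 3
IDX_RATEEQ = _N + 4
IDX_CLFIXED = _N + 5
IDX_CLI_FIX = _N + 6
IDX_CLO_FIX = _N + 7
IDX_GATE_DIFF = _N + 8
IDX_GATE_GLIA = _N + 9
IDX_DILUTION = _N + 10
IDX_IRAND = _N + 11
IDX_BETA_OVERRIDE = _N + 12  # nan -> derive from geometry
IDX_FREEZE_SLOW = _N + 13    # 1 -> only V, n, h evolve (fast subsystem)
PACK_SIZE = _N + 14

# parameter names accepted by protocol overrides (by pack slot)
OVERRIDABLE = dict(IDX)
OVERRIDABLE["beta"] = IDX_BETA_OVERRIDE


def pack(params: ModelParameters, flags: VariantFlags, r_tot_cm: float,
         vol0: float, a_ss: float) -> np.ndarray:
    """Pack parameters + flags + geometry references for the kernel."""
    v = np.empty(PACK_SIZE)
    for name, i in IDX.items():
        v[i] = getattr(params, name)
    v[IDX_RTOT] = r_tot_cm
    v[IDX_VOL0] = vol0
    v[IDX_ASS] = a_ss
    v[IDX_DYNVOL] = 1.0 if flags.dynamic_volume else 0.0
    v[IDX_RATEEQ] = 1.0 if flags.concentration_mode == "rate_equations" else 0.0
    v[IDX_CLFIXED] = 1.0 if flags.chloride_mode == "fixed" else 0.0
    v[IDX_CLI_FIX] = flags.cl_i_fixed
    v[IDX_CLO_FIX] = flags.cl_o_fixed
    v[IDX_GATE_DIFF] = 1.0 if flags.o2_gate_diffusion else 0.0
    v[IDX_GATE_GLIA] = 1.0 if flags.o2_gate_glia else 0.0
    v[IDX_DILUTION] = 1.0 if flags.dilution_flux else 0.0
    v[IDX_IRAND] = flags.irand_sd
    v[IDX_BETA_OVERRIDE] = np.nan
    v[IDX_FREEZE_SLOW] = 0.0
    return v


STATE_NAMES = ("V", "n", "h", "K_o", "Na_i", "Cl_i", "O2", "Vol",
               "K_i", "Na_o", "Cl_o")
N_STATE = len(STATE_NAMES)
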