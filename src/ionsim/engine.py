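"""Fixed-step RK4 simulation engine: protocols, traces, equilibration.

The integrator steps in ms (the membrane equation's natural unit);
protocols and traces are expressed in seconds.  Parameter overrides in a
protocol are applied between steps, never mid-step, and the base value is
restored outside each override interval.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import fsolve

from ._version import __version__ as _pkg_version
from ._kernel import rk4_integrate
from .core import FullState, derived_quantities, full_rhs
from .geometry import Geometry, geometry_from_radius, radius_from_volume
from .parameters import (
    OVERRIDABLE, STATE_NAMES, ModelParameters, VariantFlags, pack,
)


class IntegrationError(RuntimeError):
    pass


class EquilibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class Protocol:
    """Experiment schedule.

    ``schedule`` is a list of ``(t_start, t_end, parameter_name, value)``
    overrides in seconds; e.g. energy deprivation sets ``O2_inf`` to 0 on
    an interval.  ``record_stride`` is integrator steps per recorded
    sample (50 steps at the default dt = 0.02 ms -> 1 ms sampling, enough
    to resolve spikes for classification).  ``transient_discard`` marks
    how many initial seconds analyses should drop.
    """

    duration: float                       # s
    schedule: tuple = ()
    dt: float = 0.02                      # ms
    record_stride: int = 50
    transient_discard: float = 0.0        # s

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for t0, t1, name, _ in self.schedule:
            if not (0.0 <= t0 < t1 <= self.duration + 1e-9):
                raise ValueError(
                    f"override interval [{t0}, {t1}] outside [0, duration]")
            if name not in OVERRIDABLE:
                raise ValueError(f"unknown override parameter {name!r}")


@dataclass
class Trace:
    """Uniformly sampled simulation output.

    ``data`` holds time (s), the state variables, and derived columns
    (reversal potentials, pump current/flux, oxygen gate, instantaneous
    radius, percent volume change).  ``meta`` carries everything needed
    to re-run bit-identically.
    """

    data: pd.DataFrame
    meta: dict

    def __getitem__(self, col):
        return self.data[col].to_numpy()

    @property
    def t(self):
        return self.data["t"].to_numpy()

    def after(self, t0: float) -> "Trace":
        return Trace(self.data[self.data["t"] >= t0].reset_index(drop=True),
                     self.meta)

    def final_state(self, flags: VariantFlags | None = None) -> FullState:
        row = self.data.iloc[-1]
        rate_eq = (flags is not None
                   and flags.concentration_mode == "rate_equations")
        return FullState(
            V=row["V"], n=row["n"], h=row["h"], K_o=row["K_o"],
            Na_i=row["Na_i"], Cl_i=row["Cl_i"], O2=row["O2"], Vol=row["Vol"],
            K_i=row["K_i"] if rate_eq else None,
            Na_o=row["Na_o"] if rate_eq else None,
            Cl_o=row["Cl_o"] if rate_eq else None)


DERIVED_COLUMNS = ("K_i", "Na_o", "Cl_o", "V_K", "V_Na", "V_Cl", "I_pump",
                   "F_O2", "r_in", "percent_dVol")


def _derived_frame(rec: np.ndarray, params: ModelParameters,
                   flags: VariantFlags, geometry: Geometry) -> pd.DataFrame:
    from .core import (conserved_concentrations, nernst_potentials,
                       oxygen_gate, pump_rate)
    V, n, h, Ko, Nai, Cli, O2, Vol = (rec[:, i] for i in range(8))
    r_in = radius_from_volume(Vol)
    if flags.dynamic_volume:
        vol_i = Vol
        area = 4.0 * np.pi * (r_in * 1e-4) ** 2
    else:
        vol_i = np.full_like(Vol, geometry.Vol_i)
        area = np.full_like(Vol, geometry.A)
    vol_o = 4.0 * np.pi / 3.0 * geometry.r_tot_cm**3 - vol_i
    beta = vol_i / vol_o
    gamma = area / (params.F * vol_i)
    if flags.concentration_mode == "rate_equations":
        Ki, Nao, Clo = rec[:, 8], rec[:, 9], rec[:, 10]
    else:
        Ki, Nao, Clo = conserved_concentrations(Nai, Ko, beta, params,
                                                strict=False)
    cli = np.full_like(Cli, flags.cl_i_fixed) \
        if flags.chloride_mode == "fixed" else Cli
    clo = np.full_like(Clo, flags.cl_o_fixed) \
        if flags.chloride_mode == "fixed" else Clo
    with np.errstate(invalid="ignore", divide="ignore"):
        v_k = params.nernst_scale * np.log(Ko / Ki)
        v_na = params.nernst_scale * np.log(Nao / Nai)
        v_cl = params.nernst_scale * np.log(cli / clo)
    f_o2 = oxygen_gate(O2)
    j_pump = pump_rate(Nai, Ko, f_o2, params)
    r_ss = radius_from_volume(_ref_vol(geometry))
    pct = ((r_in**3 - r_ss**3) / r_ss**3) * 100.0
    return pd.DataFrame(dict(K_i=Ki, Na_o=Nao, Cl_o=clo, V_K=v_k,
                             V_Na=v_na, V_Cl=v_cl, I_pump=j_pump / gamma,
                             F_O2=f_o2, r_in=r_in, percent_dVol=pct))


def _ref_vol(geometry: Geometry) -> float:
    import math
    r_ss = math.sqrt(geometry.A_ss / (4.0 * math.pi))
    return 4.0 * math.pi / 3.0 * r_ss**3


def nominal_state(geometry: Geometry, params: ModelParameters) -> FullState:
    """The nominal resting state used to start full-model runs: normal
    ion concentrations, gates at their voltage steady states, volume at
    the reference geometry."""
    from .core import h_infinity, n_infinity
    v0 = -65.0
    return FullState(V=v0, n=float(n_infinity(v0)), h=float(h_infinity(v0)),
                     K_o=4.0, Na_i=params.Na_i_rest, Cl_i=7.0,
                     O2=params.O2_inf - 0.1, Vol=geometry.Vol_i,
                     K_i=params.K_i_rest, Na_o=params.Na_o_rest, Cl_o=132.0)


def integrate(state0: FullState, protocol: Protocol,
              params: ModelParameters, flags: VariantFlags,
              geometry: Geometry, derived: bool = True) -> Trace:
    """Integrate the model under a protocol and return a Trace.

    ``derived=False`` skips the auxiliary columns (reversal potentials,
    pump current, implied radius, ...) for sweep workloads that only
    need the state variables; ``percent_dVol`` and ``r_in`` are still
    provided (the classifier uses them).
    """
    pvec = pack(params, flags, geometry.r_tot_cm, _ref_vol(geometry),
                geometry.A_ss)
    dt = protocol.dt
    stride = protocol.record_stride

    # segment boundaries where the active override set changes
    times = {0.0, protocol.duration}
    for t0, t1, _, _ in protocol.schedule:
        times.update((t0, min(t1, protocol.duration)))
    bounds = sorted(times)

    y = state0.to_vector()
    rec_all = []
    t_all = []
    t_offset = 0.0
    aborted = None
    rng = np.random.default_rng(flags.seed)
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = pvec.copy()
        for t0, t1, name, value in protocol.schedule:
            if t0 <= a < t1:
                seg[OVERRIDABLE[name]] = value
        n_steps = int(round((b - a) * 1000.0 / dt))
        if n_steps == 0:
            continue
        seed = int(rng.integers(0, 2**31 - 1))
        rec, y, status = rk4_integrate(y, seg, dt, n_steps, stride,
                                       flags.irand_sd, seed)
        tseg = t_offset + np.arange(len(rec)) * dt * stride / 1000.0
        if rec_all:
            rec, tseg = rec[1:], tseg[1:]   # drop duplicated boundary sample
        rec_all.append(rec)
        t_all.append(tseg)
        if status != 0:
            aborted = float(tseg[-1]) if len(tseg) else a
            break
        t_offset = a + n_steps * dt / 1000.0

    rec = np.vstack(rec_all)
    t = np.concatenate(t_all)
    df = pd.DataFrame(rec[:, :8], columns=list(STATE_NAMES[:8]))
    df.insert(0, "t", t)
    if derived:
        # K_i/Na_o/Cl_o live in the derived frame (identical to the
        # state slots in the rate-equation variant)
        df = pd.concat([df, _derived_frame(rec, params, flags, geometry)],
                       axis=1)
    else:
        r_in = radius_from_volume(rec[:, 7])
        r_ss = radius_from_volume(_ref_vol(geometry))
        df["r_in"] = r_in
        df["percent_dVol"] = ((r_in**3 - r_ss**3) / r_ss**3) * 100.0

    cfg = dict(params=dataclasses.asdict(params),
               flags=dataclasses.asdict(flags),
               geometry=dict(r_in=geometry.r_in, r_tot=geometry.r_tot,
                             A_ss=geometry.A_ss),
               protocol=dict(duration=protocol.duration,
                             schedule=[list(s) for s in protocol.schedule],
                             dt=protocol.dt,
                             record_stride=protocol.record_stride,
                             transient_discard=protocol.transient_discard),
               state0=dataclasses.asdict(state0))
    meta = dict(config=cfg, seed=flags.seed, version=_pkg_version,
                config_hash=hashlib.sha256(
                    json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16])
    trace = Trace(df, meta)
    if aborted is not None:
        err = IntegrationError(
            f"non-finite state at t ~ {aborted:.3f} s; "
            "last valid state retained in the partial trace")
        err.partial_trace = trace
        raise err
    return trace


def equilibrate(params: ModelParameters, flags: VariantFlags,
                geometry: Geometry, relax_s: float = 200.0,
                tol: float = 1e-9) -> FullState:
    """Resting state: relaxation integration followed by a Newton polish.

    Volume is held at the geometry's value (the solved state defines the
    osmotic reference Vol_initial and A_ss for subsequent dynamic-volume
    runs).  Raises EquilibrationError when the residual does not meet
    ``tol`` (per-ms derivatives).
    """
    fixed = flags.replace(dynamic_volume=False, irand_sd=0.0)
    rate_eq = fixed.concentration_mode == "rate_equations"
    if rate_eq:
        # the rate-equation closure has a conserved-total redundancy, so
        # its fixed points form a family; seed Newton at the conservation
        # rest to select the member consistent with the closed variant
        cons = equilibrate(params,
                           fixed.replace(concentration_mode="conservation"),
                           geometry, relax_s, tol)
        d = derived_quantities(cons, params,
                               fixed.replace(concentration_mode="conservation"),
                               geometry)
        cons.K_i, cons.Na_o, cons.Cl_o = d["K_i"], d["Na_o"], d["Cl_o"]
        y = cons.to_vector()
    else:
        proto = Protocol(duration=relax_s, record_stride=1000)
        tr = integrate(nominal_state(geometry, params), proto, params, fixed,
                       geometry)
        y = tr.final_state(fixed).to_vector()

    cl_dyn = fixed.chloride_mode == "dynamic"
    idx = [0, 1, 2, 3, 4]
    if cl_dyn:
        idx.append(5)
    idx.append(6)
    if rate_eq:
        idx.extend([8, 9, 10])

    def residual(z):
        yy = y.copy()
        yy[idx] = z
        st = FullState.from_vector(yy, rate_eq)
        return full_rhs(st, params, fixed, geometry)[idx]

    sol, info, ier, msg = fsolve(residual, y[idx], full_output=True,
                                 xtol=1e-13)
    res = np.max(np.abs(residual(sol)))
    if res > tol:
        raise EquilibrationError(
            f"equilibration residual {res:.2e} exceeds {tol:.0e} "
            f"({msg}); check parameters")
    y[idx] = sol
    return FullState.from_vector(y, rate_eq)


def run_energy_deprivation(r_in0: float, ed_minutes: float,
                           params: ModelParameters, flags: VariantFlags,
                           pre_s: float = 200.0, post_s: float = 400.0,
                           dt: float = 0.02) -> Trace:
    """Energy-deprivation protocol: settle the full model at normal bath
    conditions, set the perfusate O2 to zero for ``ed_minutes``, then
    restore it and follow recovery (or its failure)."""
    geo = geometry_from_radius(r_in0)
    fl = flags.replace(dynamic_volume=True)
    ed = ed_minutes * 60.0
    proto = Protocol(
        duration=pre_s + ed + post_s,
        schedule=((pre_s, pre_s + ed, "O2_inf", 0.0),),
        dt=dt, transient_discard=0.0)
    tr = integrate(nominal_state(geo, params), proto, params, fl, geo)
    tr.meta["ed_interval"] = [pre_s, pre_s + ed]
    return tr


def run_seizure_sd(r_in0: float, params: ModelParameters,
                   flags: VariantFlags, duration: float = 400.0,
                   dt: float = 0.02) -> Trace:
    """Full-model run (dynamic volume) from the nominal resting state at
    elevated reservoir K+; produces the spontaneous seizure-to-SD
    transition for radii in the seizure-prone band."""
    geo = geometry_from_radius(r_in0)
    fl = flags.replace(dynamic_volume=True)
    proto = Protocol(duration=duration, dt=dt)
    return integrate(nominal_state(geo, params), proto, params, fl, geo)
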