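"""Fast-subsystem (V, n, h) bifurcation analysis with frozen slow variables.

The slow variables [K]o, [Na]i, [Cl]i, [O2], and volume are frozen and
the remaining three-dimensional membrane subsystem analyzed as a function
of [K]o: equilibrium branches with stability, limit points (LP), Hopf
bifurcations (HB), and the limit cycle's termination type (SNIC when the
cycle dies at the fold with diverging period; homoclinic (HC) when the
period diverges away from the fold on the middle branch).  Special points
are located by scanning plus bisection rather than arclength
continuation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, fsolve

from .core import (gating_rates, h_infinity, m_infinity, n_infinity,
                   nernst_potentials, oxygen_gate, pump_rate)
from .engine import Trace
from .geometry import geometry_from_radius
from .parameters import ModelParameters


@dataclass(frozen=True)
class FrozenSlow:
    """The frozen slow variables of the fast subsystem."""
    Na_i: float = 18.0
    Cl_i: float = 8.0
    O2: float = 30.0
    r_in: float = 4.82    # sets geometry (gamma for the pump current)


@dataclass
class Equilibrium:
    K_o: float
    V: float
    n: float
    h: float
    stable: bool
    eigenvalues: np.ndarray


@dataclass
class SpecialPoint:
    kind: str        # 'LP' | 'HB' | 'SNIC' | 'HC' | 'undetermined'
    K_o: float
    V: float | None = None


@dataclass
class FastSubsystemDiagram:
    frozen: FrozenSlow
    K_o: np.ndarray
    equilibria: list            # list of lists of Equilibrium per K_o
    special_points: list        # list of SpecialPoint
    cycle_K_o: np.ndarray = field(default_factory=lambda: np.empty(0))
    cycle_vmax: np.ndarray = field(default_factory=lambda: np.empty(0))
    cycle_vmin: np.ndarray = field(default_factory=lambda: np.empty(0))
    cycle_period: np.ndarray = field(default_factory=lambda: np.empty(0))


def _fast_env(K_o, frozen: FrozenSlow, params: ModelParameters):
    """Reversal potentials and the constant pump current for frozen slow
    variables; [K]i and [Na]o follow the conservation closure."""
    geo = geometry_from_radius(frozen.r_in)
    k_i = params.K_i_rest + (params.Na_i_rest - frozen.Na_i)
    na_o = params.Na_o_rest - geo.beta * (frozen.Na_i - params.Na_i_rest)
    cl_o = K_o + na_o + 2.0 * params.Ca_o - params.A_o
    v_k, v_na, v_cl = nernst_potentials(K_o, k_i, na_o, frozen.Na_i,
                                        cl_o, frozen.Cl_i,
                                        params.nernst_scale)
    f_o2 = oxygen_gate(frozen.O2)
    i_pump = pump_rate(frozen.Na_i, K_o, f_o2, params) / geo.gamma
    return v_k, v_na, v_cl, i_pump


def fast_rhs(y, K_o, frozen: FrozenSlow, params: ModelParameters):
    """Right-hand side of the (V, n, h) subsystem (per ms)."""
    v, n, h = y
    v_k, v_na, v_cl, i_pump = _fast_env(K_o, frozen, params)
    m = m_infinity(v)
    i_na = -params.gNa_bar * m**3 * h * (v - v_na)
    i_k = -params.gK_bar * n**4 * (v - v_k)
    i_l = (-params.gKL_bar * (v - v_k) - params.gNaL_bar * (v - v_na)
           - params.gClL_bar * (v - v_cl))
    am, bm, an, bn, ah, bh = gating_rates(v)
    return np.array([
        (i_na + i_k + i_l - i_pump) / params.C,
        params.phi * (an * (1 - n) - bn * n),
        params.phi * (ah * (1 - h) - bh * h)])


def _scalar_balance(v, K_o, frozen, params):
    """Current balance at n = n_inf(V), h = h_inf(V): its roots are the
    fast-subsystem equilibria."""
    return fast_rhs(np.array([v, float(n_infinity(v)), float(h_infinity(v))]),
                    K_o, frozen, params)[0]


def _jacobian(y, K_o, frozen, params, eps=1e-6):
    """Central finite-difference Jacobian of the fast subsystem."""
    J = np.empty((3, 3))
    for j in range(3):
        e = np.zeros(3)
        e[j] = eps
        J[:, j] = (fast_rhs(y + e, K_o, frozen, params)
                   - fast_rhs(y - e, K_o, frozen, params)) / (2 * eps)
    return J


def _scalar_balance_vec(vs, K_o, frozen, params):
    v_k, v_na, v_cl, i_pump = _fast_env(K_o, frozen, params)
    m = m_infinity(vs)
    n = n_infinity(vs)
    h = h_infinity(vs)
    return (-params.gNa_bar * m**3 * h * (vs - v_na)
            - params.gK_bar * n**4 * (vs - v_k)
            - params.gKL_bar * (vs - v_k) - params.gNaL_bar * (vs - v_na)
            - params.gClL_bar * (vs - v_cl) - i_pump)


def find_equilibria_fast(K_o: float, frozen: FrozenSlow,
                         params: ModelParameters,
                         v_range=(-150.0, 30.0), n_scan: int = 1500,
                         tol: float = 1e-9) -> list:
    """Equilibria of the fast subsystem at one [K]o.

    Roots of the scalar current balance (with gates at their V-steady
    states) are bracketed on a scan grid, refined by brentq, and polished
    by a 3-D Newton solve; stability comes from the eigenvalues of the
    finite-difference Jacobian.  Returns an empty list when no root lies
    in the scan range.
    """
    vs = np.linspace(*v_range, n_scan)
    f = _scalar_balance_vec(vs, K_o, frozen, params)
    eqs = []
    for i in np.flatnonzero(np.sign(f[:-1]) * np.sign(f[1:]) < 0):
        v0 = brentq(_scalar_balance, vs[i], vs[i + 1],
                    args=(K_o, frozen, params), xtol=1e-12)
        y0 = np.array([v0, float(n_infinity(v0)), float(h_infinity(v0))])
        y, info, ier, _ = fsolve(fast_rhs, y0, args=(K_o, frozen, params),
                                 full_output=True, xtol=1e-13)
        if ier != 1 or np.max(np.abs(fast_rhs(y, K_o, frozen, params))) > tol:
            continue
        if eqs and abs(y[0] - eqs[-1].V) < 1e-6:
            continue
        eig = np.linalg.eigvals(_jacobian(y, K_o, frozen, params))
        eqs.append(Equilibrium(K_o, y[0], y[1], y[2],
                               bool(np.max(eig.real) < 0), eig))
    return eqs


def _hb_criterion(K_o, branch_v_guess, frozen, params):
    """Max real part of the complex eigenvalue pair on the branch
    containing ``branch_v_guess`` (nan when the branch is absent)."""
    eqs = find_equilibria_fast(K_o, frozen, params)
    if not eqs:
        return np.nan, None
    eq = min(eqs, key=lambda e: abs(e.V - branch_v_guess))
    cplx = eq.eigenvalues[np.abs(eq.eigenvalues.imag) > 1e-8]
    if len(cplx) == 0:
        return np.nan, eq
    return float(np.max(cplx.real)), eq


def _cycle_features(K_o, frozen, params, t_max=4.0, transient=1.0,
                    v0=-20.0, dt=0.02):
    """Limit-cycle extrema and period from direct simulation of the fast
    subsystem with the slow variables frozen (None when the trajectory
    settles to an equilibrium)."""
    from ._kernel import rk4_integrate
    from .parameters import IDX_FREEZE_SLOW, pack
    from .parameters import VariantFlags as _VF
    geo = geometry_from_radius(frozen.r_in)
    pv = pack(params, _VF(), geo.r_tot_cm, geo.Vol_i, geo.A_ss)
    pv[IDX_FREEZE_SLOW] = 1.0
    y0 = np.zeros(11)
    y0[:8] = [v0, float(n_infinity(v0)), float(h_infinity(v0)), K_o,
              frozen.Na_i, frozen.Cl_i, frozen.O2, geo.Vol_i]
    stride = max(1, int(round(0.1 / dt)))       # 0.1-ms sampling
    rec, _, status = rk4_integrate(y0, pv, dt,
                                   int(round(t_max * 1000.0 / dt)),
                                   stride, 0.0, 0)
    if status != 0:
        return None
    t = np.arange(len(rec)) * dt * stride / 1000.0
    v = rec[:, 0]
    m = t > transient
    if not m.any():
        return None
    vv, tt = v[m], t[m]
    if vv.max() - vv.min() < 2.0:
        return None
    thr = 0.5 * (vv.max() + vv.min())
    ups = tt[1:][(vv[1:] > thr) & (vv[:-1] <= thr)]
    if len(ups) < 3:
        return None
    period = float(np.mean(np.diff(ups)))
    return float(vv.max()), float(vv.min()), period


def one_parameter_fast_diagram(K_o_grid, frozen: FrozenSlow,
                               params: ModelParameters,
                               period_cap: float = 2.0
                               ) -> FastSubsystemDiagram:
    """V-vs-[K]o diagram of the fast subsystem.

    Locates LP (fold of the equilibrium count), HB (bisection on the
    real part of the complex eigenvalue pair along the depolarized
    branch), and the cycle-termination type: the termination [K]o is
    approached geometrically from inside the oscillatory window, and the
    blow-up of the period classifies it as SNIC (within 0.05 mM of the
    fold) or HC (elsewhere); if the period cap is reached without
    localization the point is labeled 'undetermined'.
    """
    K_o_grid = np.asarray(K_o_grid, dtype=float)
    eq_per_ko = [find_equilibria_fast(k, frozen, params) for k in K_o_grid]
    special = []

    # LP: change in the number of equilibria (fold of the lower/middle pair)
    counts = np.array([len(e) for e in eq_per_ko])
    lp_ko = None
    for i in range(len(K_o_grid) - 1):
        if counts[i] >= 3 and counts[i + 1] < 3:
            lo, hi = K_o_grid[i], K_o_grid[i + 1]
            for _ in range(40):
                mid = 0.5 * (lo + hi)
                if len(find_equilibria_fast(mid, frozen, params)) >= 3:
                    lo = mid
                else:
                    hi = mid
            lp_ko = 0.5 * (lo + hi)
            special.append(SpecialPoint("LP", lp_ko))
            break

    # HB on the depolarized branch: bracket a sign change of Re(lambda)
    hb_ko = None
    upper_guess = -30.0
    res = [(k, _hb_criterion(k, upper_guess, frozen, params)[0])
           for k in K_o_grid]
    res = [(k, r) for k, r in res if np.isfinite(r)]
    for (k0, r0), (k1, r1) in zip(res[:-1], res[1:]):
        if r0 * r1 < 0:
            lo, hi, rlo = k0, k1, r0
            for _ in range(40):
                mid = 0.5 * (lo + hi)
                rm, _eq = _hb_criterion(mid, upper_guess, frozen, params)
                if not np.isfinite(rm):
                    break
                if rm * rlo <= 0:
                    hi = mid
                else:
                    lo, rlo = mid, rm
            hb_ko = 0.5 * (lo + hi)
            _, eq = _hb_criterion(hb_ko, upper_guess, frozen, params)
            special.append(SpecialPoint("HB", hb_ko,
                                        eq.V if eq else None))
            break

    # limit cycle along the grid
    c_ko, c_max, c_min, c_per = [], [], [], []
    for k in K_o_grid:
        feat = _cycle_features(k, frozen, params)
        if feat is not None:
            c_ko.append(k)
            c_max.append(feat[0])
            c_min.append(feat[1])
            c_per.append(feat[2])

    # cycle termination at the low-[K]o end: approach geometrically
    if c_ko:
        k_in = c_ko[0]                       # inside the oscillatory window
        k_out = K_o_grid[K_o_grid < k_in][-1] if np.any(K_o_grid < k_in) \
            else k_in - 0.2
        periods = []
        k_lo, k_hi = k_out, k_in
        term_ko = None
        for _ in range(30):
            mid = 0.5 * (k_lo + k_hi)
            feat = _cycle_features(mid, frozen, params,
                                   t_max=2.0 * period_cap)
            if feat is None or feat[2] > period_cap:
                k_lo = mid
            else:
                k_hi = mid
                periods.append(feat[2])
            if k_hi - k_lo < 1e-4:
                term_ko = 0.5 * (k_lo + k_hi)
                break
        if term_ko is None:
            special.append(SpecialPoint("undetermined", k_hi))
        else:
            growing = len(periods) >= 2 and periods[-1] > periods[0]
            if not growing:
                special.append(SpecialPoint("undetermined", term_ko))
            elif lp_ko is not None and abs(term_ko - lp_ko) < 0.05:
                special.append(SpecialPoint("SNIC", term_ko))
            else:
                special.append(SpecialPoint("HC", term_ko))

    return FastSubsystemDiagram(frozen, K_o_grid, eq_per_ko, special,
                                np.array(c_ko), np.array(c_max),
                                np.array(c_min), np.array(c_per))


def two_parameter_fast_curves(K_o_grid, Na_i_grid, Cl_i_values,
                              params: ModelParameters,
                              frozen: FrozenSlow = FrozenSlow()):
    """Trace LP/HB/SNIC/HC locations over a [Na]i grid for each [Cl]i.

    Returns ``{Cl_i: {kind: [(Na_i, K_o), ...]}}``; per-point failures
    leave gaps.
    """
    curves = {}
    for cl_i in Cl_i_values:
        kind_pts = {}
        for na_i in Na_i_grid:
            fz = FrozenSlow(Na_i=float(na_i), Cl_i=float(cl_i),
                            O2=frozen.O2, r_in=frozen.r_in)
            try:
                diag = one_parameter_fast_diagram(K_o_grid, fz, params)
            except Exception:
                continue
            for sp in diag.special_points:
                kind_pts.setdefault(sp.kind, []).append(
                    (float(na_i), float(sp.K_o)))
        curves[float(cl_i)] = kind_pts
    return curves


def project_trace(trace: Trace):
    """Project a Trace onto the ([K]o, [Na]i) plane for overlay on the
    two-parameter diagrams."""
    return trace["K_o"], trace["Na_i"]
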