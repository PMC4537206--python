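# Methods

## The model

`ionsim` simulates a single spherical neuron of radius `r_in` inside a
fixed spherical shell of radius `r_tot = 5 µm`. The membrane carries
Hodgkin–Huxley transient Na⁺ and delayed-rectifier K⁺ currents plus K⁺,
Na⁺, and Cl⁻ leaks, all written inward-positive:

    C dV/dt = I_Na + I_K + I_KL + I_NaL + I_ClL − I_pump (+ I_rand)
    I_Na = −g_Na m³h (V − V_Na),  I_K = −g_K n⁴ (V − V_K), ...
    dq/dt = φ [α_q(V)(1−q) − β_q(V) q],  q ∈ {n, h};  m = m_∞(V)

with the standard rate functions (α_m singular point at −30 mV and α_n
at −34 mV filled with their analytic limits) and φ = 3. The membrane is
coupled to four slow ionic balances — extracellular K⁺, intracellular
Na⁺ and Cl⁻, and local O₂ — and, optionally, to osmotic volume
dynamics. Reversal potentials follow Nernst with RT/F = 26.64 mV. Under
the default *conservation closure* the partner concentrations are
algebraic:

    [K]i = 140 + (18 − [Na]i)
    [Na]o = 144 − β([Na]i − 18)
    [Cl]o = [K]o + [Na]o + 2[Ca]o − [A]o      (132 mM at rest)

where β = Vol_i/Vol_o. The fluxes are: Na/K-ATPase transport
J_pump = F(O₂)·ρ·σ(Na_i)·(K_o/(K_o+3.5))² (ρ = 1.25 mM/s, σ the logistic
with midpoint 25 mM and slope 3 mM), whose electrogenic current in the
membrane equation is J_pump/γ with γ = A/(F·Vol_i); glial buffering
F(O₂)·B_glia·logistic(K_o; 18, 2.5); reservoir exchange
F(O₂)·ε_K·([K]o − [K]o,∞) with ε_K = 0.33 s⁻¹; and KCC2 cotransport
ρ_KCC·ln([K]i[Cl]i/[K]o[Cl]o). O₂ obeys
d[O₂]/dt = (−α·J_pump + ε_O([O₂]∞ − [O₂]))/τ, with consumption shut off
when the local pool is empty so [O₂] ≥ 0. F(O₂) is the logistic with
midpoint 16 mg/L and width 4 mg/L; it gates the pump, the glia, and (by
default) the reservoir diffusion — the last two gates are what allow
anoxic depolarization.

Volume relaxes toward the osmotic target
`Vol̂ = Vol₀(1.1029 − 0.1029·exp((π_o−π_i)/20))` (π the total
osmolarities including impermeant anions [A]i = 132.1, [A]o = 18 mM and
fixed Ca²⁺) with time constant τ_v; conductance densities are rescaled
by A_ss/A_ins so each channel population's total conductance is fixed,
and β, γ follow the instantaneous geometry. Concentrations are *not*
renormalized by volume changes by default (the dilution fluxes exist as
an off-by-default toggle).

### Calibration of the pump and diffusion constants

The pump form above is a reconstruction. Three structural facts pin it:
(i) the resting Na⁺ balance — the Na⁺ leak (g_NaL = 0.02 mS/cm² at
V ≈ −60 mV gives ≈ 2.5 µA/cm² of influx) must be matched by three times
the pump flux, ≈ 0.055 mM/s, which simultaneously sets the electrogenic
current near 0.9 µA/cm² and thereby places the fast-subsystem fold just
above the 8 mM bath; (ii) the conservation closure amplifies any
quiescent deviation of [Na]i from 18 mM by β in [Na]o, so for β ≳ 8 the
osmotic balance forces quiescent [Na]i ≈ 18.0 at both 4 and 8 mM bath
K⁺, which requires a shallow (Hill-type) K⁺ dependence rather than a
steep logistic; (iii) event termination and recovery need the pump to
saturate severalfold above its resting flux at elevated [K]o and [Na]i.
The Hill half-saturation of 3.5 mM and ρ = 1.25 mM/s are the values of
the model's biophysical lineage and satisfy all three constraints.
ε_K = 0.33 s⁻¹ is likewise the lineage value; a Fick's-law helper
(2D/Δx²) is provided, but literal neocortical-diffusivity inputs yield a
rate so large it clamps [K]o to the bath and abolishes every oscillatory
regime. τ_v is interpreted in seconds: the volume must lag the 30–100 s
seizure cycle for the seizure-to-SD transition to depend on it at all
(at millisecond relaxation the volume is slaved to the osmotic target
and τ_v is dynamically irrelevant).

### Time scales and integration

V, n, h are fast (ms); [K]o and [Na]i intermediate (seconds); [Cl]i and
[O₂] slow (tens of seconds); volume infra-slow (τ_v, default 50 s). The
system is integrated with a fixed-step classical RK4 compiled with
numba; dt = 0.02 ms resolves spikes and keeps the post-event
hyperpolarized excursions (where the gating rates are stiffest) stable.
Protocol parameter changes happen between steps, never mid-step; the
optional Gaussian background current is redrawn once per step and held
through the four stages. Traces record every 50 steps (1 ms) by
default, enough to detect spikes. A high-accuracy adaptive integrator
(SciPy) over the same right-hand side serves as convergence oracle in
the tests, never in production runs.

`equilibrate()` finds resting states by relaxation plus a Newton polish
(hybrid solve; finite differences). In the rate-equation variant the
fixed points form a one-parameter family (the extra ODEs conserve
totals), so the Newton solve is seeded at the conservation-closure rest
to select the comparable member. Full-model seizure/SD runs start from
a nominal resting state ([Na]i = 18, [K]o = 4, [Cl]i = 7 mM, gates at
their V-steady-states, volume at the initial geometry) rather than from
a Newton-solved bath-4 rest: at large β the solved rest has
[Na]i ≈ 19.8 mM, and the β-amplified closure then mis-sets the osmotic
reference by tens of mM, producing a spurious initial volume jump.

## What the simulated conditions reproduce — and what they do not

With the reservoir at 8 mM K⁺ (the standard seizure-induction
condition) the fixed-volume radius sweep reproduces the four-region
structure: resting below ≈ 4.62 µm, small-amplitude periodic seizures
with peak [K]o growing to ≈ 12.6 mM, an abrupt explosion to
high-amplitude SD-capable orbits at ≈ 4.80 µm, and silence again above
≈ 4.96 µm. The full model with dynamic volume shows the spontaneous
seizure→SD transition, recurrent SD with post-event hyperpolarization
and pump-driven [K]o undershoot, weak (recovering) anoxic
depolarization at r_in = 4 µm versus strong (non-recovering,
Donnan-like) AD at 3 µm, suppression of AD by fixed Cl⁻ or ungated
reservoir diffusion, and glial-buffering suppression of SD above
≈ 20–26 mM/s.

Known quantitative deviations of the reconstruction (all reported
honestly by `scripts/acceptance.py`): the amplitude-jump radius sits
at ≈ 4.81 µm rather than ≈ 4.826 µm, so a run started at r_in0 =
4.81 µm the first seizure runs away into SD within ~2 s instead of
completing a 12.9-mM-ceiling seizure first — the seizure-phase peak
[K]o and the osmotically implied swelling radius measured at exactly
those prescribed radii therefore overshoot; the strong-AD plateau sits
near −9 mV rather than −2 mV; and the upper silent state is a focus
with a ~0.3–1 mM subthreshold [K]o ripple rather than a node, so
"silent" is operationalized as: no spikes, no high-amplitude orbit, and
[K]o amplitude < 1 mM.

## Classification

Spikes are upward crossings of −20 mV with a 2-ms refractory. A seizure
is ≥ 5 spikes with median inter-spike interval < 0.5 s, terminated by a
2-s spike-free gap or SD onset. An SD plateau is V > −40 mV sustained
> 5 s with < 2 spikes/s, recovering below −50 mV; AD is a plateau
beginning inside an energy-deprivation interval; a plateau persisting
to the end of the record is depolarized-locked. The SD threshold is
−40 mV (not −30) because the plateau in this parameterization
oscillates around −35 ± 10 mV. A [K]o amplitude of 0.1 mM separates
genuine orbits from ripple in sweep diagrams. All thresholds are
config-exposed (`ClassificationRules`).

## Bifurcation analysis

Sweep diagrams integrate each parameter value independently from the
nominal resting state, discard a 150-s transient, and record
post-transient extrema plus the behavioral label; with rare events
(periods beyond ~100 s near regime boundaries) the recorded window is
the limiting factor, so boundary radii carry an uncertainty of roughly
one grid step. The fast subsystem (V, n, h with frozen [K]o, [Na]i,
[Cl]i, [O₂], volume) is analyzed by a vectorized scalar-balance scan
with brentq bracketing, 3-D Newton polish, and stability from the
eigenvalues of a central-difference Jacobian (step 1e-6). Folds (LP)
are located by bisection on the equilibrium count, Hopf points by
bisection on the real part of the complex pair along the depolarized
branch, and cycle termination by geometric approach of the cycle
boundary with a period-growth check: period divergence within 0.05 mM
of the fold is labeled SNIC, elsewhere HC, and a capped period without
localization is labeled undetermined. There is no pseudo-arclength
continuation; the scan-plus-bisection approach reproduces the special
points the analysis needs.

## Parameters that matter most

| parameter | default | unit | role |
|---|---|---|---|
| `r_in` | varies | µm | cell radius; the order parameter of the analysis |
| `K_o_inf` | 4 | mM | reservoir K⁺; 8 mM is the seizure-induction condition |
| `rho` | 1.25 | mM/s | max pump transport; sets rest, fold position, recovery |
| `B_glia` | 5 | mM/s | glial buffering; ≈ 21–26 suppresses SD |
| `eps_K` | 0.33 | s⁻¹ | reservoir coupling; larger values clamp [K]o |
| `tau_v` | 50 | s | volume relaxation; < ~25 s prevents the SZ→SD transition |
| `O2_inf` | 30 | mg/L | perfusate O₂; 0 is the energy-deprivation condition |

## Limitations

Single compartment, no synapses, no GHK formulation, no NKCC1, no
astrocyte swelling or Ca²⁺ dynamics, no tissue-level propagation. The
pump/diffusion constants are a constrained reconstruction, not a fit to
data; regime boundaries are accurate to a few hundredths of a µm at
best and all conclusions should be read at that resolution.
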