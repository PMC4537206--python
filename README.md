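# ionsim

A single-neuron simulator for the unified dynamics of epileptic seizure
(SZ), spreading depression (SD), and anoxic depolarization (AD).

**Who it is for.** Computational neurophysiologists studying how the ionic
microenvironment and cell swelling shape pathological membrane dynamics:
why the same neuron can rest, seize, lock into a depolarized SD plateau,
or fail to recover from anoxia, depending only on its size, its
extracellular space, its glial support, and its oxygen supply.

**The model.** A spherical neuron of radius *r*ᵢₙ inside a fixed shell
(*r*ₜₒₜ = 5 µm) with Hodgkin–Huxley spiking coupled to dynamic ion
concentrations, oxygen, and osmotic volume:

- membrane: C dV/dt = I_Na + I_K + I_L − I_pump, with
  I_Na = −g_Na m³h (V − V_Na), I_K = −g_K n⁴ (V − V_K), three leaks, and
  gating dq/dt = φ[α_q(1−q) − β_q q];
- ion balances for [K]ₒ, [Na]ᵢ, [Cl]ᵢ driven by the channel fluxes, an
  oxygen-limited Na/K-ATPase (flux J_pump, electrogenic current
  J_pump/γ with γ = A/(F·Volᵢ)), glial K⁺ buffering, diffusion to a
  distant reservoir, and KCC2 cotransport; [K]ᵢ, [Na]ₒ, [Cl]ₒ closed by
  conservation, e.g. [Na]ₒ = 144 − β([Na]ᵢ − 18) with β = Volᵢ/Volₒ;
- local oxygen d[O₂]/dt = (−α·J_pump + ε_O([O₂]∞ − [O₂]))/τ, gating the
  pump, the glia, and the reservoir diffusion through a sigmoid F([O₂]);
- osmotic volume dVol/dt = (Vol̂ − Vol)/τ_v with
  Vol̂ = Vol₀(1.1029 − 0.1029·e^{(π_o−π_i)/20}), conductances rescaled to
  conserve each channel population's total conductance.

Because β and γ depend on the radius, cell volume acts as an order
parameter: sweeping *r*ᵢₙ at seizure-inducing reservoir K⁺ (8 mM) yields
resting → periodic seizures → an abrupt explosion to SD-capable
high-[K]ₒ orbits → resting again, and the full model swells itself
spontaneously from the seizure regime into SD. Setting the perfusate O₂
to zero produces AD, recoverable or not depending on cell size. See
`docs/methods.md` for the equations, the calibration of the pump, and
known quantitative deviations.

## Worked example

```python
import ionsim as isim

params = isim.ModelParameters(K_o_inf=8.0)   # seizure-inducing bath K+
trace = isim.run_seizure_sd(4.81, params, isim.VariantFlags(),
                            duration=260.0)
cl = isim.classify_trace(trace, transient=0.0)
print(cl.label)
for e in cl.events:
    print(f"{e.kind}: t=[{e.t_on:.1f},{e.t_off:.1f}] s, "
          f"peak [K]o = {e.peak_K_o:.1f} mM, "
          f"peak dVol = {e.peak_pct_dvol:.1f} %")
```

prints

```
SD-mixed
SZ: t=[120.7,123.1] s, peak [K]o = 35.1 mM, peak dVol = 0.6 %
SD: t=[123.3,128.7] s, peak [K]o = 55.5 mM, peak dVol = 1.6 %
```

i.e. after two minutes of slow [K]ₒ/[Na]ᵢ build-up the cell fires one
seizure, runs up extracellular K⁺ far past the seizure ceiling, locks
into a depolarized SD plateau while the (slowly relaxing) volume swells,
and then recovers with a deep pump-driven hyperpolarization — the
spontaneous SZ→SD transition. See `docs/methods.md` for how these
numbers relate to the model's [K]ₒ ceilings.

The same work from a shell:

```
ionsim run   --config cfg.json --out trace.csv
ionsim ed    --r-in 3.0 --minutes 5 --out ad.csv
ionsim sweep --param r_in --grid 4.5:5.0:0.01 --out diagram.csv
ionsim fastbif --na-i 18,24,29,32 --cl-i 8 --out fast.csv
ionsim classify trace.csv
```

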