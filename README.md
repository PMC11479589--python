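# optoclock

Simulation and entrainment analysis of light-controllable repressilator gene
clocks in bacteria.

## The problem

The repressilator — a ring of three transcription factors in *E. coli*, each
repressing the next — gives individual cells a robust genetic clock, but
cell-to-cell variability in growth rate disperses the oscillation periods and
an initially synchronized culture dephases within a few cycles: the
population-averaged reporter signal damps away even though every single cell
keeps oscillating. Adding an optogenetic module that expresses an extra,
light-driven copy of one repressor (LacI, under a green/red-switchable
CcaS–CcaR promoter) turns the clock into an *optorepressilator*: green light
arrests the ring at a known state, and short periodic green pulses act as a
zeitgeber that advances or delays each cell's phase, locking a whole
heterogeneous population to the light rhythm.

This package is for modellers and synthetic biologists who want to simulate
that system, compute its phase response curve, predict entrainment with
circle-map theory, and test period/damping estimators on realistic synthetic
plate-reader and mother-machine data.

## The model

Protein concentrations in units of the repressor–promoter dissociation
constant K:

    dx/dt  = β / (1 + zⁿ)        − α·x
    dy/dt  = β / (1 + (x + x′)ⁿ) − α·y
    dz/dt  = β / (1 + yⁿ)        − α·z
    dx′/dt = β′(t)               − α·x′

with dilution rate α = 0.75 h⁻¹, production rate β = 300 h⁻¹, Hill
coefficient n = 3, and a light-dependent rate β′(t) (80 h⁻¹ under green, 0
under red). In the digital limit (n → ∞) the free cycle has amplitude β/α and
period T₀ = 3 ln(β/α)/α; green light breaks the limit cycle whenever
β′/α > 1 and parks the system at (x, y, z, x′) = (0, 0, β/α, β′/α).

Entrainment by a pulse train of period T_L is described by the circle map
φₙ₊₁ = φₙ + T_L/T₀ − 1 + Δφ(φₙ), where Δφ(φ) is the single-pulse phase
response curve; entrained states are fixed points Δφ(φ*) ≡ 1 − T_L/T₀ (mod 1)
with PRC slope in (−2, 0).

## Worked example

```python
import optoclock as oc

params = oc.OptoParams()                      # α=0.75, β=300, n=3, β′=80
T0 = oc.natural_period(params)
print(f"T0 = {T0:.2f} h")                     # T0 = 17.51 h

prc = oc.compute_prc(params, tau=2.0, beta_prime_pulse=80.0, T0=T0)
state = oc.entrained_phase(prc, TL=0.9 * T0)  # forcing 10% fast
print(f"phi* = {state.phi_star:.3f}, slope = {state.slope:.2f}")
# phi* = -0.051, slope = -1.73

tone = oc.frequency_ratio(params, f_over_nu0=2.0, beta_prime=80.0, nu0=1 / T0)
print(f"nu/f = {tone.ratio:.3f}")             # nu/f = 0.500
```

The natural period lands at the experimentally calibrated ≈17.5 h. Forcing
10% faster than the natural rhythm entrains the oscillator with the pulse
arriving 0.051 cycles *before* the reporter peak (on the rising edge, where a
pulse advances the clock), at a map-stable slope. Forcing at twice the
natural frequency locks the oscillator on the 1:2 Arnold tongue: its dominant
spectral peak sits at exactly half the forcing frequency.

A command-line interface mirrors the library (`optoclock simulate|ensemble|
prc|entrain|tongues|synth|validate`); every run writes its artifacts plus a
`manifest.json` from which it can be reproduced bit-for-bit.

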