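# Methods

## Model

The package integrates the protein-only optorepressilator: three repressors
x, y, z on a ring plus a light-driven copy x′ of the first repressor that
adds to x in repressing y. Concentrations are in units of the dissociation
constant K; all promoters share the production rate β and Hill coefficient n;
decay is purely dilution at the growth rate α. The light input enters only
through the production rate β′(t) of x′ (no explicit photochemistry, no
mRNA stage, no stochastic gene expression). Red light is modelled as β′ = 0:
the calibrated construct's dark-state leakage is below background, and
leakage regimes are out of scope beyond the break condition β′/α > 1.

Default parameters (units of h⁻¹ except n): α = 0.75, β = 300, n = 3,
β′ = 80 under green. These place the free-running period at ≈17.5 h. The
digital-limit formulas — amplitude β/α, period 3 ln(β/α)/α — are exposed as
closed forms and used as convergence oracles: the simulated period's gap to
the digital value shrinks monotonically as n grows (27% at n = 3, 2.6% at
n = 20).

## Integration

Forward Euler with a fixed step, default dt = 0.005 h. The scheme is chosen
deliberately: the system is non-stiff at these parameters, a fixed grid makes
piecewise-constant light protocols exact (β′ is sampled at the left endpoint
of each step, so pulse edges snap to the grid), and accuracy is verified
rather than assumed — peak times move by well under 0.5% when dt is halved,
and the decoupled x′ component is compared against its closed-form
exponential relaxation (`relaxation_check`; defect < 0.1 K-units at
dt = 0.001 over 20 h). With non-negative initial states and dt < 1/α the
update preserves non-negativity exactly. Trajectories are bit-reproducible;
the time-rescaling symmetry (α, β, β′, t) → (cα, cβ, cβ′, t/c) holds to the
bit for c = 2 on binary-representable grids.

The default initial state is the post-green reset (0, 0, β/α, 0): the state
a cell leaves green light in, lying on the limit cycle's entry path, so
free-running transients last under two cycles.

## Phase response and entrainment

Phase zero is the y (TetR/CFP) expression peak; "pulse arrival" means pulse
onset, matching how pulses are marked against reporter traces. A shift is
measured by running an unperturbed reference and a pulsed copy from the same
state, reading the peak-time difference at the third peak after the pulse
(transients decay within about one cycle; a test verifies the shift is
unchanged at the fifth peak), in units of the natural period.

Peak times determine the shift only mod 1. The curve's branch is resolved by
continuity: values are anchored in the small-shift delay region (φ ≈ +0.25)
and unwrapped along the phase axis. This matters because the model's advance
branch is large — a pulse arriving well before the y peak effectively
re-anchors the clock to the pulse (the light-driven LacI must decay below K,
≈6 h at these parameters, before y can rise), an advance that exceeds half a
cycle for φ ≲ −0.15 and would alias to a spurious delay under hard mod-1
wrapping. With the branch resolved, the curve is advance-positive for φ < 0
and delay-negative for φ > 0, with a narrow dead zone around the crossover,
which sits slightly past the peak (φ ≈ +0.035) rather than exactly at it.
Convenience mod-1 views are recovered by `wrap_phase`.

Entrained states are fixed points of the circle map
φₙ₊₁ = φₙ + T_L/T₀ − 1 + Δφ(φₙ). Because the map lives on the circle, the
fixed-point condition is solved mod 1: Δφ(φ*) ≡ 1 − T_L/T₀. Roots are
bracketed on a 2048-point scan of the linearly interpolated 64-point curve
and bisected to 10⁻⁴ cycles; stability requires the central-difference slope
in (−2, 0).

Measuring the entrained phase from a simulated pulse train needs care on the
advance side: there the pulse itself truncates the y rise and creates the
peak, so a naive pulse-to-nearest-peak offset saturates at zero. The
implementation instead marks each cycle by its rise onset (upward crossing of
20% of the trace's range — untouched by the pulse) and adds the free-running
onset-to-peak delay, recovering the phase the map reasons about; on the
delay side this coincides with the naive measurement. Entrainment is
declared only if the per-pulse phases stay within 0.15 cycles; otherwise a
drift flag is raised.

Known limitation: the first-order map underestimates the principal tongue on
the fast-forcing side. At T_L/T₀ = 0.8 the required advance falls where the
curve's slope is below −2, so the map classifies every fixed point as
unstable, yet the full ODE still locks 1:1 there (visible in the tongue
surface). Within T_L/T₀ ∈ [0.9, 1.1] map and ODE agree to better than 0.01
cycles.

## Ensembles and the dephasing metric

Populations are independent cells (no coupling, no division bookkeeping)
differing only in α, drawn i.i.d. normal with mean 0.75 h⁻¹ and s.d.
0.034 h⁻¹ (multiwell-culture preset) or 0.071 h⁻¹ (mother-machine preset,
where no competition suppresses slow growers); non-positive draws are
redrawn. Default ensemble size is 200 cells — large enough to keep
Monte-Carlo noise on envelope metrics below a few percent at desk-scale
runtime. Three initial conditions are provided: the post-green reset, the
IPTG-arrested state (β/α, β/α, 0, 0), and random phases sampled uniformly
along each cell's own cycle (per-cell period estimated from the digital
formula rescaled by the simulated-to-digital ratio at the mean growth rate).

The dephasing half-life metric counts the oscillation periods until the
population-mean amplitude halves. Amplitude is the peak-to-trough contrast
of each cycle (peak height minus the following minimum), the quantity a
plate-reader trace's "high-contrast oscillation" refers to; an envelope
referenced to the signal's long-run mean would overstate the decay, because
the dephased mean settles far above the early troughs. The crossing time is
interpolated linearly between bracketing peaks and divided by the mean peak
spacing; an undamped signal reports infinity. The metric reproduces the
closed-form value 2.5 on exp(−t/τ_d)·cos(2πt/T) with τ_d = 2.5 T/ln 2, and
gives ≈2.3–2.6 periods (seed-dependent) for the default dispersed ensemble.

Under resonant pulsing the population first relaxes from the fully
synchronized start into its steady entrained phase distribution — fast cells
spread along the shallow delay branch, slow cells bunch on the steep advance
branch (growth rate and entrained phase correlate at r ≈ 0.9) — so envelope
constancy is asserted after an 8-cycle transient; thereafter the contrast is
flat (late/early ratio ≈ 1.0) where the free-running ensemble decays to a
few percent.

## Spectral locking analysis

The locking observable is ν/f: the dominant peak of the mean-subtracted,
unwindowed periodogram of y (transient discarded) over the forcing
frequency. No window is needed since only the arg-max bin of a long,
near-periodic record is consumed; a documented heuristic guards against
harmonic confusion by preferring half the arg-max frequency when that bin
holds ≥25% of the maximum power. Runs cover 40 forcing periods with 10
discarded (tests use 21/5; an even analysed count keeps f/2 on the frequency
grid). Default scan grids: f/ν₀ ∈ [0.4, 2.4] step 0.1, β′ ∈ {0, 10, 20, 40,
80, 120} h⁻¹, τ = 2 h. Plateaus are labelled where |ν/f − p/q| < 0.02
(twice the spectral resolution) for p/q ∈ {1, 1/2, 2, 3/2, 2/3}; unforced
(β′ = 0) cells are never labelled, since locking is undefined without
forcing. On the 1/2 tongue, cells peak on either even or odd pulses
depending on initial phase; a population holding both parities averages to a
small oscillation at f itself, which the alternate-peak classifier
demonstrates (cells whose post-transient peak-to-pulse assignment is
inconsistent are counted unlocked and excluded).

## Synthetic measurements

The generator emulates two instruments: a plate reader observing the
population mean every 2 h, and a mother machine observing single cells every
9 min (0.15 h). Observed fluorescence is gain × y + baseline + additive
Gaussian noise whose s.d. is a fraction (default 0.05, matching error bars
"comparable to symbol size") of the truth signal's full range. Not modelled:
reporter maturation (y is read directly), photobleaching, segmentation
artifacts, OD normalisation. Consequently, passing recovery tests shows the
estimators are sound against sampling and additive noise — not against
reporter dynamics or instrument drift in real data. Period recovery smooths
densely sampled traces with a 1 h boxcar before peak detection (symmetric,
so peak positions are unbiased) and achieves <2% error on the mother-machine
preset and <5% on the coarse plate-reader preset at 5% noise.

## Problem sizes

Default analyses run at desk scale: single-cell runs of 40–60 forcing
periods, ensembles of 200 cells over ~8 free-running periods, PRC grids of
64 phases evaluated in one vectorised batch against a shared reference, and
tongue scans of a few hundred cells × grid nodes. These sizes keep every
quantity's Monte-Carlo and spectral resolution comfortably inside the
tolerances asserted in the tests.
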