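# Methods

## Model

The Na⁺ conductance is a Hodgkin–Huxley product `I_Na = G_Na (V−E_Na) m³ h s`
with three independent gating processes:

* **Activation (m).** Boltzmann steady state `m∞ = 1/(1+exp((V−V½)/k))`
  with V½ = −35 mV, k = −7 mV and a sigmoid time constant
  `τ_m(V) = 0.03 + 0.1/(1+exp((V+30)/10))` ms.
* **Fast inactivation (h).** The two-state scheme A ⇌ I with rates
  derived from the Boltzmann steady state (V½ = −62 mV, k = +6 mV) and
  the bell-shaped `τ_h(V) = 0.35 + 16/(exp((V+60)/10)+exp(−(V+60)/10))` ms
  through α_h = h∞/τ_h and β_h = (1−h∞)/τ_h.  An optional
  `alpha_h_scale` multiplies α_h to model recovery-accelerating
  mutations; it shifts the apparent availability midpoint by k·ln(scale).
* **Slow inactivation (s).** An independent two-state gate
  (V½ = −55 mV, k = +8 mV, `τ_s(V) = 500 + 4000/(2cosh((V+50)/15))` ms),
  kept outside the extended fast-inactivation scheme.

**Persistent current.** A persistent fraction `P_persist ∈ [0,1]` is
imposed by the rate transformation β′ = (1−P)β, α′ = α + Pβ.  Two exact
consequences are used as invariants: α′+β′ = α+β (the apparent fast
time constant is untouched) and the depolarized steady state of the
available state equals P exactly (h′∞ = P + (1−P)h∞).

**Drug binding.** The blocker binds only to the fast-inactivated state:
A ⇌ I ⇌ I_drug with pseudo-first-order association λ·[drug] and
dissociation μ; defaults λ = 10 μM⁻¹s⁻¹, μ = 1 s⁻¹ (K_D = 0.1 μM),
converted to per-ms internally.  Binding carries no voltage dependence
and there is no direct A ↔ I_drug edge, so at hyperpolarized voltages
the only escape from I_drug is unbinding followed by fast I → A
recovery; this is what produces the dominant slow recovery component
(≈785 ms here, i.e. 1/μ shortened slightly by rebinding through I).

## Numerics

* **Voltage clamp.** Voltages are piecewise constant, so each epoch is
  solved in closed form: scalar exponential relaxation for m and s, and
  the matrix exponential of the 3×3 subsystem generator via
  eigen-decomposition (exact to round-off; a scaling-and-squaring
  fallback handles numerically degenerate spectra and logs when taken).
  Traces are sampled at 0.02 ms; peaks use a 0.1 ms onset blank and the
  end-pulse measure averages the final 2 ms of the step with an open
  right edge so the first post-step sample is never included.
* **Neuron.** Fixed step dt = 0.01 ms; exponential (exact-at-frozen-V)
  updates for m, s, n; Strang splitting of the A⇌I and I⇌I_drug
  exchanges (each solved exactly over the step); Crank–Nicolson update
  for V with gate values at the half step.  Step-halving leaves spike
  counts unchanged and changes the integrated K⁺ charge by <0.5% at the
  tested injections.  Output sampling 0.025 ms; |V| > 200 mV aborts with
  a diagnostic naming the step size.
* **Exponential fits.** Sums of 1–2 exponentials are ill-conditioned,
  so initialisation uses a variable-projection grid search (log grid of
  candidate time constants, amplitudes by linear least squares) before a
  bounded Levenberg–Marquardt polish.  Fitted time constants are capped
  at 10× the longest observed interval: slower components are not
  identifiable from the window and would otherwise absorb drift.
  Model selection keeps the double exponential only when it improves
  residual RMS by >20% and both amplitude fractions exceed 5%.
* **Boltzmann fits.** Initialised from the half-crossing of the monotone
  envelope of the data and the 25–75% width, which prevents mirrored
  solutions; non-convergence is flagged, not raised.

## Default parameters and calibration

Voltage-clamp scale: G_Na = 50 nS, E_Na = +50 mV (≈1.4 nA peak at
−10 mV, comfortably inside the series-resistance rule below).  Neuron:
25 μm × 25 μm cylinder, side-wall area only (≈1963 μm², 19.6 pF at
1 μF/cm²), gNa = 150, gK = 30, gLeak = 0.4 mS/cm², E_K = −85 mV,
E_leak = −70 mV, delayed rectifier n⁴ with
α_n = 0.02(V+30)/(1−exp(−(V+30)/10)), β_n = 0.25·exp(−(V+40)/80) ms⁻¹.

These defaults were calibrated jointly, once, against the qualitative
firing behaviour the model must reproduce, and then frozen: resting
potential ≈ −70 mV, action potentials with positive overshoot and
≈1.1 ms half-width, rheobase 120 pA with a continuous 400 ms train from
140 pA, and a 5% persistent current that sustains bursting already at
120 pA while roughly doubling the K⁺ charge of a train.  Two points are
worth stating explicitly.  First, a classic squid-type rectifier placed
around −55 mV cannot support firing with a Na⁺ channel whose
inactivation midpoint (−62 mV) sits 30–40 mV below its activation
midpoint: the subthreshold approach inactivates the Na⁺ current before
ignition ("accommodation") and the K⁺ gate clamps the membrane; the
rectifier must stay closed below ≈−45 mV and τ_h must be slow enough
(here up to ≈8 ms near −60 mV) that h survives the approach to
threshold.  Second, every calibrated value is an ordinary config field,
so alternative parameterizations drop in without code changes.

**Drug at rest.** With K_D = 0.1 μM, 5 μM blocker is a 50-fold excess;
at a −70 mV rest, where ≈21% of channels are transiently inactivated,
the equilibrium drags most of the population into I_drug (available
fraction ≈7%).  The in-silico drug therefore raises rheobase
substantially (120 → 220 pA), not marginally; the direction (never
lowering rheobase) is the model's robust prediction, the magnitude
depends steeply on the resting potential relative to the availability
curve.

## Synthetic data

`navsim.synth` emulates whole-cell (HEK-like) and low-Na⁺
two-electrode-clamp (oocyte-like, E_Na = +10 mV) recordings: per-cell
lognormal draws for positive scale factors (conductance, recovery
speed, persistent fraction; CVs 0.3/0.1/0.1), normal draws for the
availability-midpoint jitter (SD 1 mV) and capacitance (15 ± 4 pF),
and additive white Gaussian sample noise (SD 5 pA).  Mutant presets
span the observed effect classes — midpoint shifts of +3/+5/+8 mV,
recovery acceleration ×1.5/2/3, persistent fractions 1/3/5%, and a 5%
expression variant.  The battery per cell: an IV family (−80…+40 mV,
70 ms steps), availability curve (100 ms prepulses −120…−10 mV; long
enough for the fast gate, short enough that the slow gate stays ≈put),
and recovery (70 ms conditioning, intervals 0.2 ms–3 s).

What the generator does **not** model — capacitive transients,
series-resistance distortion, leak subtraction artefacts, 1/f or line
noise, Na⁺-accumulation reversal shifts — bounds what passing tests
mean: parameter recovery demonstrates the correctness of the analysis
chain under the stated statistical structure, not robustness to every
artefact of real rigs.

**Persistent-fraction estimation.** The conventional end-pulse/peak
ratio overestimates P because the observed peak already carries partial
inactivation (peak h < 1); at these kinetics a true 5% channel reads
≈7% end/peak at 0 mV.  `estimate_persistent_fraction` therefore fits
`I(t) = I_ss + A·exp(−t/τ)` over the early decay and normalises the
plateau by the amplitude extrapolated to the step onset, recovering P
to <0.1 percentage points on noiseless data (median error <0.5 points
across the default noisy cohort).

**Recovery-τ scoring.** A 70 ms conditioning pulse unavoidably engages
the slow gate (~11% availability dip recovering with τ ≈ 0.8 s), so the
fitted fast component — not a forced single exponential — is compared
to the analytic 1/(α′+β′); the single-exponential check instead uses a
5 ms conditioning pulse and 2–12 ms intervals, the window in which the
m-gate has deactivated and the slow gate has not moved.

## Statistics

Group comparisons use the two-sided unpaired Student t-test
(equal-variance pooled form; Welch available via `equal_var=False`),
with star labels *, **, *** at p < 0.05, 0.01, 0.001 and "ns" at
p ≥ 0.05 (boundary value inclusive).  The recording QC rule flags any
sweep whose peak current times access resistance exceeds 5 mV
(2.5 nA × 2 MΩ at the reference settings).

## Problem sizes

Tests and the acceptance script run the full protocols at analysis
resolution but modest breadth: 31-point recovery grids, 23-voltage
availability curves, 6–12 cells per synthetic group, rheobase scans on
10–20 pA grids over the informative 60–340 pA range, and firing
simulations of 400 ms.  These sizes were chosen as the smallest at
which every assertion is comfortably away from its tolerance.

## Known limitations

Single-channel stochasticity, temperature dependence, β1-subunit
modulation, open-state or resting-state drug block, multi-compartment
morphology and extracellular K⁺ accumulation dynamics are out of scope.
The three-conductance neuron is a caricature for charge accounting and
threshold ordering, not a quantitative interneuron model.
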