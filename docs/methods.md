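# Methods

## Scope and model

The package analyses pre-steady-state redox kinetics of STEAP1/STEAP2
measured by absorbance spectroscopy. Three levels of model are used, from
data-facing to mechanistic:

1. **Empirical multi-exponential phases.** A single-wavelength trace is
   modelled as offset + Σᵢ aᵢ(1−e^(−kᵢt)) (rise; heme reduction followed at
   the ferrous Soret maximum, 427 nm) or offset + Σᵢ aᵢe^(−kᵢt) (decay;
   heme oxidation). Phase fractions are |aᵢ|/Σ|aⱼ| × 100 and always sum to
   100%. This is the quantity the secondary analyses consume.
2. **Sequential first-order chains.** Rapid-scan matrices are modelled
   bilinearly as A(t,λ) = Σⱼ cⱼ(t)·sⱼ(λ) where the cⱼ are populations of an
   irreversible chain A→B→…→Z. The chain is solved with the Bateman closed
   form; when any two effective decay constants (including the terminal 0)
   agree within 1e-6 relative, the closed form cancels catastrophically and
   the solver switches to the matrix exponential of the chain generator.
   Both routes agree to <1e-6 over rates spanning 1e-4–1e3 s⁻¹ (property
   test).
3. **Mechanistic models.** (a) Two-population pseudo-first-order oxidation:
   two enzyme conformers (fractions f₁+f₂=1), each oxidized by excess
   ferric substrate with k_obs,ᵢ = k_on,ᵢ[S] + k_off,ᵢ. Binding-then-ET is
   deliberately collapsed into this form — it is the model that the linear
   k_obs-vs-[S] analysis parameterizes, and the printed k_on/k_off have no
   meaning outside it. A warning is raised below 10× substrate excess.
   (b) The diffusible-FAD shuttle: mass-action ODEs over
   {NADPH, FAD_ox, FADH⁻ free, FADH⁻ bound, semiquinone, ferric/ferrous
   heme, Fe³⁺/Fe²⁺}. Hydride transfer is first-order in NADPH gated by the
   oxidized-FAD fraction; bound FADH⁻ reduces heme in two sequential
   one-electron steps (rate k_et each, gated by the ferric-heme fraction;
   one-step transfer is configurable since the per-event electron count is
   not established); ferrous heme reduces Fe³⁺ at k_sub with a soft
   saturation gate (K 1 μM) so the stated rate applies while substrate is
   plentiful. Electron bookkeeping — electrons held on flavin, heme and
   Fe²⁺ never exceed 2 × NADPH consumed — holds on every stored point.
   Whether reduced FAD physically diffuses between protomers or repositions
   within one cannot be distinguished kinetically; the model represents
   both as the same free/bound exchange.

## Spectra

Species spectra are sums of Gaussian bands in wavelength on a uniform grid
(default 350–700 nm, 1 nm). Band positions follow the ferric/ferrous
landmarks of the STEAP heme (Soret 413 → 427 nm; broad ferric Q band near
550 nm; ferrous α/β bands at 560/532 nm) and generic flavin bands. The
Gaussian shape and the absolute extinction scale are modelling choices, not
measured quantities — the heme extinction coefficients were determined by a
pyridine hemochrome assay whose values are not printed — so peak epsilons
default to 100 mM⁻¹cm⁻¹ (Soret) and ~10–20 (Q/α/β) and every reference
spectrum carries `epsilon_source: placeholder` metadata. Nothing downstream
depends on the absolute scale: deconvolution recovers rates and shapes, and
the empirical fits work in AU.

## Synthetic data

Every generator is a pure function of (parameters, seed); the generating
truth is embedded in the output's provenance so fits can be validated
against it. Defaults chosen once:

- photometric noise: additive Gaussian, σ = 0.002 AU — a typical
  diode-array noise floor (no noise figure is published);
- instrument dead time: 1.5 ms, a standard stopped-flow value. The
  recorded t = 0 is the end of the dead time: the mechanism is evolved for
  dead_time_s before the first sample, and the dead time is recorded in
  provenance;
- rapid-scan time grids: 400 log-spaced points, needed to resolve phases
  separated by >10³-fold in one window; single-wavelength stopped-flow
  shots use a linear 1000-point base, matching how such traces are
  acquired;
- total ΔA₄₂₇ amplitude ≈ 0.05 AU for ~1 μM heme, consistent with the
  placeholder extinction scale; the A₄₂₇ baseline offsets are likewise
  nominal;
- the FADH⁻ saturation titrations use 5 log-spaced substrate points over
  1–20 μM (the published insets do not list their concentrations);
  Fe³⁺-NTA titrations use the published series (25/75/125/175 μM for
  STEAP1, 75/125/175 μM for STEAP2);
- BLI: six analyte concentrations as published (20, 10, 5, 2.5, 1.3,
  0.6 μM); the off-rate is not printed, so the fixture uses
  k_off = 0.05 s⁻¹ (a typical Octet time scale) with k_on = k_off/K_D, and
  noise enters primarily as 2% multiplicative scatter on each trace's
  equilibrium response;
- mixing ratio 1:1 (unstated; configurable); the Fe³⁺:NTA = 1:4
  preparation ratio is metadata only — chelation chemistry is not
  modelled.

What the generators deliberately do **not** emulate: baseline drift, lamp
flicker and other photodiode-array artifacts; dithionite side reactions;
the >2 s multi-phasic complexity of STEAP2 oxidation time courses (the
generator is cleanly biphasic, which is exactly the regime the published
2-s window analysis assumes). Passing tests therefore demonstrate that the
inference chain is unbiased and precise under the stated noise model — not
that it is robust to instrument artifacts absent from the simulation.

## Fitting

**Multi-exponential fits** use variable projection: the nonlinear search
runs over log rate constants only (Levenberg–Marquardt, tolerances 1e-14),
with amplitudes and offset solved by linear least squares at every iterate.
This makes amplitude initial guesses unnecessary; multistart covers rate
seeds log-spaced between 1/(10·t_max) and 10/t_min (8/6/5 seeds for 1/2/3
phases, all combinations). Two guards: (i) solutions containing a phase
that has fully decayed before the first sample (e^(−k·t₀) < 0.01) are kept
only as a fallback — such a phase is pure aliasing into the offset; (ii)
fitted rates within 1% of each other raise a rate-collapse warning
suggesting one fewer phase. Phases are reported fast-first (ties broken by
larger amplitude); standard errors come from the Jacobian at the solution.
The baseline offset is always floated (whether the published fits floated
one is unstated). Least squares is unweighted throughout, and phase-count
selection uses AIC with a 2-unit parsimony margin, with the SSE floored at
the numerical noise of the data scale so that noiseless nested models
compare as equivalent.

**Secondary fits.** The hyperbolic law k_obs = V_max[S]/(K_M+[S]) and the
BLI dose-response law are fitted with bounded trust-region least squares; a
no-curvature warning is raised when K_M is unconstrained by the sampled
range. The linear k_obs-vs-[S] fit is ordinary least squares; the slope in
s⁻¹μM⁻¹ converts to k_on in M⁻¹s⁻¹, the intercept is k_off, and
K_D = k_off/k_on is reported in μM. A negative fitted intercept (possible
when the true off-rate is small relative to the noise) is reported with a
warning rather than clamped. BLI analysis fits each association trace with
a monophasic rise to get Req, then fits Req vs [analyte]; non-monotone Req
triggers a non-specific-binding warning.

**Global deconvolution** minimizes ‖A − C(t;k)·Sᵀ‖²_F by variable
projection: rates nonlinear, spectra solved per wavelength by nonnegative
least squares (a signed option exists for difference-spectra workflows).
The time axis is offset by the recorded dead time so the chain starts at
mixing; no unobserved fast phase is back-extrapolated beyond that. The
scale/permutation ambiguity is fixed by reporting fractional concentration
profiles (rows sum to 1) and ordering species by time of maximal
population, so converged runs from different starts agree to 1e-6. Rank
estimation counts leading singular values above 1e-3 of the largest whose
right singular vectors (spectra) have lag-1 autocorrelation above 0.8 —
signal spectra are smooth in wavelength, noise vectors are not. Degenerate
cases are contractual: a static matrix is rank 1 with a warning; a species
that never exceeds 0.1% population inherits the nearest populated species'
spectrum with an ill-conditioning warning; adjacent species with
indistinguishable spectra flag their rate as unidentifiable. Only
sequential (unidirectional) schemes are supported — the experiments
analysed here resolve only sequential species — and no rotational-ambiguity
(feasible-band) analysis is attempted; recovery is validated against
generator truth, not against any vendor program's output.

## Problem sizes

The reproduction checks use 20 seeds for the biphasic and BLI recoveries
and 10 seeds for the three-species deconvolution; rapid-scan fixtures are
400 time points × 351 wavelengths. These sizes put the stochastic means
well inside their tolerances while keeping a full run of the suite plus the
reproduction report in the minutes range on one CPU.

## Known limitations

- The ~178 s⁻¹ fast phase of the b₅R→STEAP1 reduction sits near the edge of
  the sampled window (first point 1 ms, dead time 1.5 ms); its recovery is
  correspondingly less precise than the slow phase, mirroring the large
  published uncertainty (±35 s⁻¹).
- The STEAP2/Fe³⁺-NTA analysis inherits the weak k_obs-vs-[S] dependence of
  the real data: with three concentrations and phases only ~5× apart, the
  derived K_D scatters strongly between seeds (the analysis driver reports
  this explicitly).
- Extinction scales, trace amplitudes and the BLI off-rate are nominal;
  quantities that depend only on them (absolute absorbances, Rmax) are not
  meaningful outputs.
- The shuttle model's gating functions (fraction-of-pool saturation) are a
  smooth stand-in for site-resolved binding; it reproduces limiting-rate
  behaviour, not detailed occupancies.
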