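# Methods

## Model

The community is a life-history intraguild predation (LHIGP) module:
resource `R`, consumer `C`, and a predator split into juvenile `Pj` and
adult `Pa` biomass.  All rates are mass-specific and dimensionless.

Ingestion is Holling type II.  Consumers and juvenile predators feed on
the resource only (`I_c = a_cr R / (1 + h_c a_cr R)`, likewise `I_j`
with `a_jr`, `h_p`); adults pool resource, consumers and β-discounted
conspecific juveniles in one functional response,

    I_a = (a_ar R + a_ac (C + β Pj)) / (1 + h_p (a_ar R + a_ac (C + β Pj))).

Net biomass production is `ν = σ I − T`; juvenile mortality is
`D_j = μ_p + a_ac β Pa / (…)` with the same adult denominator, so
cannibalistic mortality saturates together with adult feeding.  The
maturation rate `γ(ν_j, D_j) = (ν_j − D_j)/(1 − z^(1−D_j/ν_j))` is the
two-stage closure that makes equilibria coincide with a continuously
size-structured population growing exponentially from relative size
`z` to 1.  The four ODEs follow the standard stage-structured biomass
bookkeeping with semichemostat resource renewal `δ(R_max − R)`.

**Sign convention.** The flux tables print plain `ν` everywhere, but
the maturation function's derivation requires non-negative one-way
fluxes.  We use the standard convention: the reproduction flux into
juveniles is `ν_a⁺ Pa`, with a negative `ν_a` retained as starvation
loss in the adult equation itself, and `γ = 0` when `ν_j ≤ 0` with the
negative `ν_j` kept as juvenile biomass loss.  All equilibria analysed
here have `ν_j, ν_a ≥ 0`, so the convention only affects transient
dynamics far from equilibrium (where it prevents spurious negative
fluxes).  `γ` is evaluated exactly at its removable singularity
`ν_j = D_j` (limit `−ν_j/ln z`) via an `expm1` formulation, and
underflows to 0 when `D_j/ν_j` is so large that survival to maturation
vanishes.

## Parameters

Defaults (used everywhere unless a scenario overrides them):
`a_cr = 10`, `a_p = 6`, `ε = 0`, `h_c = 0.1`, `h_p = 0.25`, `T_c = 1`,
`T_p = 0.4`, `μ_c = 0.1`, `μ_p = 0.04`, `σ = 0.5`, `z = 0.01`,
`δ = 1`, `R_max = 3`.  Consumer constants follow quarter-power
allometry with a half-saturation constant of 1; predator constants
follow from a predator–prey body-mass ratio of 42, whose quarter-power
factor 42^(1/4) = 2.5457 is rounded to 2.5 before deriving
(h_p, T_p, μ_p) = (0.25, 0.4, 0.04) — rounding the derived constants
themselves to two significant figures would give T_p = 0.39, which is
not the standard value, so the factor is what carries the rounding.
Scenario axes: the trait `a_jr ∈ [0, a_p]`; `a_ar ∈ {0, 3, 4}` (diet
shift versus two diet-broadening settings); cannibalistic preference
`β` (0 or 1 in the core scenarios, swept to 2 in maps); productivity
`R_max` and trade-off shape `ε` in robustness grids.

## Numerical choices

* **Equilibria.** Damped Newton on the subsystem of present species,
  residual target 1e-13 in max norm (stagnation at rounding level is
  accepted up to 1e-10; anything coarser is an error).  Convergence to
  a negative density is rejected, never clamped.  Eigenvalues come from
  a central finite-difference Jacobian with step `1e-7·(1+|x|)` of the
  full four-dimensional system, so the stability flag includes the
  invasion directions of absent species.  Species presence is judged at
  1e-8 (configurable).
* **Continuation.** Secant predictor, pseudo-arclength Newton corrector,
  adaptive step with growth factor 1.3 and halving on failure; every
  corrected point is re-certified by a fixed-parameter solve.  Folds are
  detected as turns of the branch in the swept parameter and refined by
  re-parametrizing the branch locally by its fastest-varying state
  component and extremizing the parameter over it (tolerance 1e-6); the
  zero eigenvalue at the refined fold is verified in tests.  Invasion
  (transcritical) boundaries are located by bisecting the absent
  species' invasion growth rate — the per-capita growth for the
  consumer, the dominant eigenvalue of the 2×2 juvenile/adult block for
  the predator — which avoids the singular Newton systems that arise
  when continuing through a transcritical directly.  Branches truncate,
  with the boundary recorded, when a present component reaches zero.
* **Time integration.** LSODA with rtol 1e-8 / atol 1e-10.  Any
  component crossing 1e-9 from above is clamped to exactly zero and
  logged: transcritical exits leave exponentially small densities that
  must not fake persistence.  A clamped component whose inflow is
  positive (a juvenile stage fed by adult reproduction, the renewing
  resource) regrows; only dynamically dead components stay at zero.
  `find_attractor` advances in windows of 200 time units (up to 5e4),
  polishes slow endpoints with Newton, and accepts an equilibrium only
  if it is stable within the subspace of species the trajectory still
  carries — a species at exact zero cannot invade, so e.g. a
  predator-invadable consumer-resource state is still the attractor of
  a predator-free simulation.  Bounded non-convergent oscillation is
  reported as a cycle with its min/max envelope; cycles are flagged,
  never continued, because where they occur in this model their
  amplitude is negligible.
* **Invasion fitness.** The closed-form individual-level
  `R0(y′,y) = z^(D_j′/ν_j′−1) ν_a′⁺/μ_p` (0 when mutant juveniles
  cannot grow) is used instead of a dominant-eigenvalue computation on
  the mutant's linearization: it is exact, fast, and sign-equivalent —
  the identity `μ_p z^(1−D_j/ν_j) = ν_a` at the invasion boundary makes
  the R0 = 1 root coincide with the eigenvalue-based transcritical, and
  the suite verifies both this identity (to 1e-4) and resident
  neutrality `R0(y,y) = 1` (to 1e-8) along whole branches.  The
  selection gradient is a central difference with step `1e-6·a_p`
  (one-sided at the trait bounds, validated against a sympy closed-form
  derivative); second derivatives use `1e-4·a_p`, with magnitudes below
  1e-7 flagged degenerate rather than silently classified.
* **Trait evolution.** Deterministic gradient-sign steps of
  `η = 0.01·a_p` (the canonical-equation direction; waiting times are
  not modelled), with the resident equilibrium re-solved by Newton
  continuation after each step.  A gradient sign change brackets a
  singular strategy, which is then located by Brent's method and
  classified (convergence stability from the gradient's slope along the
  branch, evolutionary stability from the mutant-trait curvature of
  R0).  When the resident equilibrium disappears or acquires a real
  unstable eigenvalue, the post-transition attractor is found by time
  integration from the pre-collapse state with absent species
  inoculated at 1e-6 (an invasion-driven collapse needs the invader
  present); predator extinction there, with the re-invasion fitness
  recorded, is evolutionary suicide.  An equilibrium destabilized only
  by a complex pair (Hopf) is retained as resident: the surrounding
  small-amplitude cycle is treated as its enclosed equilibrium, which
  is what lets the noncannibalistic diet-shift trajectory proceed from
  the Hopf point (a_jr ≈ 2.97) down to the fold (a_jr ≈ 0.87) where the
  collapse genuinely happens.

## Competitive hierarchy

Closed forms anchor the scenario classification: the consumer
persistence threshold `R*_C = (T_c+μ_c)/(a_cr(σ − h_c(T_c+μ_c)))`
(0.28205 at defaults), the juvenile growth threshold
`a_jr = T_p/(R(σ − h_p T_p))` (equal to `1/R` at defaults, 3.5454 at
the consumer-resource equilibrium), and the predator's resource-only
persistence threshold `R*_P`, the root of the resource-only `R0 = 1`
(bisection; with `a_jr = a_ar = a` it reduces to
`(T_p+μ_p)/(a(σ − h_p(T_p+μ_p)))`, which is why superiority flips
exactly at `a_jr = 4` when `a_ar = 4`).  Thresholds that do not exist
are reported as infinity so orderings stay well defined.

## Scenario generation and what tests do not show

The scenario module emits the defaults, the six core (a_ar, β)
scenarios, robustness map grids over `R_max ∈ {1.5, 3, 6}` ×
`ε ∈ {−0.5, 0, 2}` (grid values beyond those named outright in the
study setup are marked as inferred), seeded uniform random parameter
sets within the admissible ranges (`ε` floored at −0.9, clear of the
trade-off's pole at −1), and seeded multiplicative state perturbations.
The model is a deterministic ODE system: randomization exists only to
exercise the code from many starting points, not to emulate biological
noise, demographic stochasticity, or environmental forcing.  Passing
tests therefore demonstrate internal consistency of the deterministic
model and reproduction of its analytic structure — not robustness of
the biological conclusions to stochasticity, space, or additional
species, which are outside the model.

## Problem sizes

The default test-and-reproduction setup uses continuation steps of
0.005–0.02 on sweeps over `a_jr ∈ [0, 6]`, trait steps of 0.06, map
grids of a few dozen cells, and attractor integrations up to 5·10^4
time units; the full suite and the threshold script each run in well
under a minute on one core.  All tolerances above are configurable
through function arguments.

## Known limitations

* Limit cycles are detected and flagged, never continued; quantitative
  statements about the oscillatory region are limited to its existence.
* Dimorphic (post-branching) evolutionary dynamics, stochastic
  trait-substitution sequences, and co-evolution of `β`, `a_ar` or `ε`
  are not modelled; each scenario holds them fixed.
* The two-parameter region maps rely on multi-start attractor searches
  (four canonical plus seeded random starts per cell); a basin missed
  by every start would go unreported, though none of the documented
  bistabilities requires more than the canonical starts.
* Stability is assessed for equilibria only; basins of attraction are
  probed by seeded perturbation, not mapped.
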