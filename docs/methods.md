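# Methods

## Protocol

All analyses follow one protocol. A constant stimulus `E₀ = E₀_init` is
applied for `t < 0` until the cascade reaches its activated steady state;
at `t = 0` the stimulus is removed and the relaxation toward the
deactivated state is recorded. The output is the phosphorylated form of
the last layer (`M₂^p`; free doubly-phosphorylated `M₂^pp` in the
mass-action model). The response duration ϑ is the half-life: the first
`t > 0` at which the output equals half its pre-stimulus steady value.

Units are arbitrary but must be consistent (one concentration unit, one
time unit); every derived quantity is dimensionless or in those units.

## Models and assumptions

**Nonlinear cascade.** Layer `i` converts substrate between inactive and
active forms. The simplifications are the classical ones for this model
family: enzyme–substrate complexes are negligible, the back-reaction from
complexes is ignored, and each layer's active phosphatase level is
constant, so dephosphorylation is first order with rate `β_i`. Substrate
conservation `M_i + M_i^p = M_i^tot` is then structural: only the active
forms are integrated, and "conservation" violations can only come from
the integrator (checked in tests at solver tolerance). The pre-stimulus
steady state has the closed-form forward recursion
`g_i = 1/(1 + (β_i/α_i)/g_{i-1})`; it is also the long-time limit of the
stimulated kinetics (verified against integration at 1e-6 relative).
The N-stage generalization repeats the per-layer pattern verbatim; three
stages is the default.

**Normalization and linearization.** Dividing each state by its steady
value gives the normalized system with `m_i^p(0) = 1`; dropping the
saturation term linearizes it about the origin (the only post-stimulus
equilibrium). The output of the linear chain is computed exactly by a
Bateman-type recursion over polynomial-times-exponential terms. Rates
that coincide within relative tolerance 1e-9 are snapped to a shared
representative and handled by the confluent `t^p e^{-βt}` form rather
than by perturbing them; this keeps the closed form exact for tied rates
(ties are otherwise undefined in the distinct-rate formula). The
closed form is validated against direct integration of the linear ODEs at
1e-8 relative.

**Mass-action MAPK model.** Ten enzymatic steps
`E + S ⇌(a,d) ES →(k) E + P`: one phosphorylation/dephosphorylation pair
in layer 0 and two pairs in each of layers 1 and 2 (double
phosphorylation, the source of ultrasensitivity). 22 species: 8 free
substrate forms, 4 free enzymes, 10 complexes. Per-layer substrate totals
and per-enzyme totals are conserved by construction. The stimulated
steady state is found by integrating over doubling time windows until the
maximum relative state change across a window is below 1e-9 (capped at
t = 1e9, reported with the residual on failure).

**Stimulus removal in the mass-action model.** The literature protocol
says only that the stimulus is removed at `t = 0`. Default (`hard`): free
`E₀` and the `E₀·M₀` complex are deleted and the substrate bound in that
complex returns to the free unphosphorylated pool, preserving substrate
conservation; this realizes "the input enzyme is set to zero" exactly.
The alternative `free_only` removes only free `E₀` and lets existing
complexes turn over. The two differ only in a transient of order the
complex lifetime.

**Output bookkeeping.** Whether phosphatase-bound output
(`P₂·M₂^pp`) should count toward `g₂` and the response is not determined
by the protocol; the default counts the free form only, and
`include_bound_output=True` switches to free + bound. At the default
parameters the bound fraction is below 1% of the total.

## Numerical choices

* Integrator: stiff-capable adaptive methods (`LSODA` for the cascade,
  `BDF` for the mass-action model), `rtol = 1e-8`,
  `atol = 1e-12 × max(totals)`.
* Sampling: 600 uniform points in `τ = log₁₀ t` on `[-2, 4 + log₁₀ 6]`
  (upper edge `t = 6×10⁴`); at this density doubling the grid changes the
  similarity integral by under 1e-4.
* Half-life: the first downward crossing of half the initial output is
  bracketed on a 2000-point log-spaced scan of the dense solution, then
  refined by Brent's method to 1e-8 relative; if no crossing occurs by
  the horizon the search extends it 100-fold once, then reports the
  half-life unresolved. A 200 000-point bisection oracle agrees with the
  refined root to well under 1e-4 relative in tests.
* Logarithmic gain: central difference of `log₁₀ y` against `log₁₀ x`
  with step 0.05 decades (a quarter of the default sweep step), exact for
  power laws. Sweep tables also carry the coarser grid-difference gain
  (step 0.2, one-sided at the ends); `refined_gain=True` re-evaluates the
  half-life at ±0.05 decades around each grid point so that robust-interval
  edges do not depend on grid coarseness.
* Similarity: trapezoid rule on the τ grid. The conventional L² norm
  (with square root) is the default because the measure is defined as a
  norm; the un-rooted squared-difference integral, which is how the
  defining display is sometimes written, is available via
  `use_sqrt=False`. Profiles are compared raw by default; a normalized
  option exists for cross-model comparison.
* Activation: strict `g₂ > 0.5`; the threshold is configurable since its
  exact value is not essential to any qualitative result.
* "β_k ≪ α_k" in the third duration-robustness condition is
  operationalized as `β_k/α_k < 0.1`; the factor is configurable since
  no cutoff is canonical.
* `beta_max` exploits that `1/g₂` is affine in any single `β_i`, solving
  the activation boundary from two evaluations; a log-space bisection is
  used for the mass-action model, where no closed form exists. The affine
  solve carries ~1e-9 relative cancellation error at extreme parameter
  ratios.

## Synthetic parameter generation

No published table of rate constants ships with this package; the
generators emulate the *organization* reported for MAPK-like cascades —
fast kinase catalysis, phosphatase rates fast–slow–fast across the three
layers, strong activation — and are labelled as emulated, not as anyone's
measured values.

`heinrich_base` fixes the slow middle phosphatase at `β₁ = 0.01` (inverse
time units; it sets the relaxation timescale), the flanking phosphatases
100× faster, and effective kinase activities `(10⁵, 3, 10⁴) × β₁`,
i.e. ≈ `(1000, 0.03, 100)`. The middle value is deliberately small: in a
real MAPK cascade the layer-1 kinase is the phosphorylated layer-0
substrate, which is hundreds of times scarcer than the downstream
substrates, so its effective activity is far below the catalytic speed.
That scarcity caps the largest activating middle-layer phosphatase rate
(`β₁^max = α₁(α₂/β₂ − 1)/(1 + β₀/α₀) ≈ 30`) close to the flanking rates,
which is what makes the rate-limiting module sensitive *everywhere*: with
a uniformly fast kinase vector (all `α = 1000`), `β₁^max` rises to ~10⁶
and a genuine duration-robust window opens for `β₁` between ~2 and ~10³ —
a mathematically correct but qualitatively different regime. The default
therefore reproduces the characteristic structure: robust intervals for
the two flanking phosphatase sweeps, none for the middle one, activation
`g₂ ≈ 0.99`, the three duration-robustness conditions satisfied for
modules 0 and 2 and the rate-limiting condition violated for module 1.
Per-seed jitter (±0.05 decades per rate) varies the sets without crossing
any of these constraints.

`hf_base` gives all ten mass-action steps one Michaelis scale
(`a = 1000`, `d = k = 150`, so `K_m = 0.3`), substrate totals
`(0.3, 1.2, 1.2)`, phosphatase totals fast–slow–fast around `1e-4`–`1e-2`,
and scales the stimulus up by decades (bounded search) until the
stimulated steady state is activated; the search is part of the generator
contract, not a fit.

`random_ensemble` samples rates log-uniformly on `[1e-4, 1e4]` and
filters to caller-supplied predicates (activation, distinct rates, ...),
reporting failure if acceptance falls below 1%.

What the generators do **not** emulate: measured rate constants,
temperature/pH dependence, crowding, scaffolding, feedback, or crosstalk.
Passing tests therefore demonstrate properties of the model class under
the stated kinetic organization, not quantitative predictions for any
particular pathway.

## Scope of the sweep protocols

A sweep covers a descending log grid (default `10⁴ → 10⁻³·⁶`, step 0.2;
39 points) of one rate or total, recomputing steady state, trajectory,
half-life, similarity-to-previous-profile, and gain at each point;
failures at single points are recorded and never abort the sweep.
Reported per sweep: maximal contiguous activated sub-intervals with
`|gain| < 0.3`, the largest activating rate (`beta_max`), the crossover
below which the swept rate is the minimum (rate-limiting onset), and the
three-condition report. These problem sizes — 39-point sweeps, 600-point
τ grids, three-stage cascades — are the package defaults and keep a full
three-sweep protocol under a few seconds for the cascade models and under
a minute for the mass-action model.

## Known limitations

* The half-life is the only event detected; dose–response analysis and
  other event types are out of scope, as are SBML I/O, Michaelis–Menten
  reductions of the mass-action model, stochastic kinetics, feedback
  loops, and information-theoretic similarity measures.
* The duration approximation `ϑ ≈ log(2c_k)/β_k` requires `c_k > 1/2`
  and degrades when rates are comparable; its 5% agreement with the
  root-found half-life is only guaranteed at ~100× rate separation.
* The gain of the last-layer phosphatase approaches −1 below its
  crossover only logarithmically slowly (through the `log(2c_k)` factor),
  so grid-difference gains near a crossover should be read qualitatively.
* Upstream shielding of `beta_max` is exact only for the perturbed
  module itself (linearity of the closed form); for downstream modules
  the residual dependence is of order `β_k/α_k`.
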