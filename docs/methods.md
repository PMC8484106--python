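# Methods

## Model

Between fires the vegetation follows the one-sided Lotka–Volterra system

    dx/dt = x (1 − x − α y),    dy/dt = δ y (1 − y),

with grass `x` and trees `y` rescaled by their carrying capacities and
time by the grass growth rate (`nondimensionalize` performs the
conversion from dimensional growth rates and capacities; a grass growth
rate of about 1/yr makes one nondimensional time unit a year). Trees
inhibit grass; grass does not inhibit trees. For the default α = 0.8,
δ = 0.6 the undisturbed system has a single globally attracting
forest–grass state at (1−α, 1): the ODE alone is never bistable.

Fire is an instantaneous kick applied every τ time units to the state
just before the fire:

    x ← (1 − k₁) x,    y ← (1 − k₂ ω(k₁ x)) y,    ω(ξ) = ξ²/(a² + ξ²).

`k₁` is the grass mortality per fire, `k₂` the maximum tree mortality,
and ω throttles tree mortality by the fuel actually burned: below the
threshold `a` fires barely touch the canopy, above it they remove close
to the full `k₂` fraction. The flow-kick map Φ = kick ∘ flow(·, τ) maps
post-fire states to post-fire states; its fixed points are periodic
solutions of the impulsive system.

### State convention

All fixed points, social values and rasters report the **map state**,
i.e. the biomass just after a fire. This is the state the closed forms
live on (the grassland fixed point `x_g = (1−(1−k₁)e^τ)/(1−e^τ)` is a
map state), and every analytic identity in the package is expressed in
it. The biomass just before a fire — sometimes the more natural
management quantity — is recovered by `pre_kick_state`, which flows the
map state forward one inter-fire interval.

## Parameters

| parameter | meaning | units | default | why |
| --- | --- | --- | --- | --- |
| α | tree-on-grass inhibition | — | 0.8 | weak enough that the ODE has a stable savanna |
| δ | tree/grass growth-rate ratio | — | 0.6 | trees recover more slowly than grass |
| a | fuel threshold of ω | grass biomass fraction | 0.08 | fires percolate once ~8% of grass capacity burns |
| k₁ | grass mortality per fire | proportion | — | regime input, in [0, 1) |
| k₂ | max tree mortality per fire | proportion | — | regime input, in [0, 1) |
| τ | inter-fire interval | nondimensional time | — | regime input, > 0 |

`k₁ = 1` or `k₂ = 1` are rejected at construction: the closed forms and
the inverse kick divide by the survival fractions. α = 0 is admitted as
the decoupled edge case in which the grass dynamics are exactly the
scalar logistic flow-kick system, used as a 1D oracle in the tests.

## Numerics

**Flow.** The tree equation is logistic and solved exactly. Given the
tree path, the grass equation is a Bernoulli equation; with
μ(t) = e^t (1 + y₀(e^{δt} − 1))^{−α/δ} its solution is
x(t) = x₀ μ(t) / (1 + x₀ ∫₀ᵗ μ). The single remaining integral is
analytic in t and evaluated by 64-point Gauss–Legendre quadrature,
composed over sub-intervals of at most 2 time units (the flow is a
semigroup, so composition is exact). The result agrees with scipy's
adaptive RK45 at rtol = atol = 1e−12 to ~5e−13 and is two to three
orders of magnitude faster per evaluation, vectorized over arbitrary
batches of states; the RK45 route is retained (`flow_rk45`) as an
independent cross-check and is exercised against the quadrature route in
the test suite. Backward-time flow (used for stable manifolds) uses the
same formulas with negative t; states above carrying capacity blow up in
finite reverse time, which surfaces as a `FlowError` and truncates the
affected trace. Batched solvers use a non-raising variant that turns
blown-up rows into NaN so one bad point cannot poison a batch.

**Jacobians.** Map Jacobians are central finite differences with step
1e−6 (relative above 1); on an axis the stencil switches to a
second-order one-sided form so evaluations stay in the quadrant. The
analytic partials at the forest and grassland states,
∂U/∂x(0,1) = (1−k₁)e^{(1−α)τ} and ∂V/∂y(x_g,0) = e^{δτ}(1−k₂ω(ξ_g)),
are reproduced to better than 1e−6 and anchor the transcritical tests.

**Fixed points.** `newton_fixed_point` is a damped Newton iteration on
Φ(s) − s with up to ten step halvings per iteration and a guard box
[−0.05, 1.5]² outside which iterates are rejected; the default residual
tolerance is 1e−10. `enumerate_fixed_points` multistarts the (batched)
Newton solver from a 20×20 lattice over [0, 1.2]² plus four analytic
seeds — origin, forest, grassland (when it exists), and the underlying
coexistence point — merges duplicates within 1e−6, and sorts by (x, y),
so the census is deterministic and idempotent. An independent check
exploits the logistic tree flow: at a fixed point the tree coordinate is
a closed-form function of the grass coordinate, reducing the coexistence
census to a scalar root scan (`coexistence_fixed_points_1d`); the two
routes agree to 1e−8 in the tests.

**Stability.** Eigenvalue moduli against 1 with a band λ_tol = 1e−7;
anything inside the band is flagged `marginal` rather than silently
classified, and region classifications built on a marginal census carry
a `boundary` flag. Eigenvalues were observed to cross the unit circle
only through +1 in the explored parameter ranges (transcriticals and
folds); no flip or torus bifurcations are searched for.

**Continuation.** Branches of fixed points are continued by
pseudo-arclength: secant predictor, Newton corrector orthogonal to the
running tangent (the tangent itself is the SVD null vector of the 2×3
residual Jacobian), and step length adapted in [1e−4, 5e−2] by corrector
performance. A fold is flagged when the tangent's parameter component
changes sign, localized by step-halving bisection to |Δparam| ≤ 1e−5,
then certified by Newton on the extended system
[Φ(s) − s; det(DΦ − I)] = 0 together with a nonzero quadratic
normal-form coefficient ½ w·D²Φ[v,v] (second difference along the
critical eigenvector v, left eigenvector w normalized to w·v = 1).
Transcritical loci are crossed transparently — the corrector matrix
stays regular because of the arclength row — and show up as stability
exchanges along the branch.

**Region taxonomy.** A regime is classified by its census signature
(forest stability, grassland stability or absence, multiset of
coexistence stabilities) against the eight-entry catalogue; unmatched
signatures return `unclassified` with the census attached rather than
guessing. The stability diagrams rasterize this per cell and overlay the
two analytic transcritical curves, the grass-existence curve, and a fold
curve traced by continuing the high-grass coexistence branch in k₁ at
each τ, seeded from bistable cells.

**Critical tree mortality.** The minimum k₂ on the grassland
transcritical surface is found by L-BFGS-B from a fixed 24×12 lattice of
starts over the reparameterized admissible strip
k₁ = frac·(1−e^{−τ}), frac ∈ (0,1), τ ∈ (0.001, 20); the restart spread
at the optimum is reported and is ~1e−11.

**Basins.** Cells are iterated in batch; a cell is assigned when its
iterate either settles (map displacement < 1e−6, then matched within
1e−4) or enters a capture radius of 1e−2 around an attractor. The
capture radius is far below the separation of any two attractors and
exists because near a fold the slow attractor's eigenvalue approaches 1,
where displacement-based convergence alone would exceed any reasonable
iteration cap. The invariant axes converge to axis states that may be
2D saddles; such cells count as converged but belong to no stable basin
(label −1).

**Manifolds and the slow region.** Saddle manifolds are grown from a
geometric fundamental domain of 20 points at 1e−4 along each eigenvector
— forward iteration for the unstable pair, inverse map (inverse kick,
then reverse flow) for the stable pair — with early termination when a
generation stalls. The "slow region" has no standard quantitative
definition; here it is the set of cells whose per-map-step displacement
is below 0.1× the window median and which lie within
max(local displacement, one cell diagonal) of the central saddle's
unstable-manifold trace. The threshold is recorded in the output.

**Resilience.** The social value of a regime is the grass biomass of its
highest-grass stable fixed point (identity valuation; no general f(x)).
Hysteresis sweeps iterate from the previously tracked state at each
parameter step — attractor tracking, not global optimization — and log
transitions when the tracked grass value jumps by more than 0.1. The
transient comparison interprets the 30-year horizon in nondimensional
time (years for a grass growth rate of 1/yr), applies
floor(horizon/τ) kicks to a deterministic lattice of initial conditions
restricted to the target basin, and counts agreement within 5% of the
long-term value, with an absolute floor of 1e−3 whenever the long-term
value is below 0.02 (the relative band is meaningless at zero grass).
These conventions are echoed in the result metadata.

**Continuous comparisons.** Three continuous-fire systems are provided:
the true small-interval limit (fire intensities r₁ = k₁/τ, r₂ = k₂/τ
held fixed as τ → 0), in which the switching function kills the tree
mortality term; and two structural analogues with Hill-type continuous
tree mortality driven by standing grass or by burned grass. The limit is
verified directly: difference quotients of the map converge to the
limit field at first order in τ (Richardson estimate over
τ = 2⁻³…2⁻¹²). The mean-limit system is never bistable; the
burned-grass variant reproduces, cell for cell in stable-state
combinations, the impulsive (k₁,k₂) diagram at fixed τ — the
quantitative form of the claim that fire *frequency* effects require the
impulsive description.

## Problem sizes

Default rasters are 100×100 (configurable); the test suite and
acceptance script use 60–80 cells per axis for basins, a 20×20×20 grid
for the three-parameter census (with a 12×12 Newton lattice per cell),
and 13–25 cells per axis for comparison scans. These sizes leave every
reported quantity stable to well inside its assertion tolerance while
keeping a full run in minutes on one core.

## Known limitations

- Fire timing is strictly periodic and spatially homogeneous; no
  stochastic ignition, no age structure, no spatial spread.
- Only period-1 fixed points of the map are sought; no evidence of
  higher-period orbits appeared in the explored ranges, but none was
  searched for.
- Cusp points are reported as meeting points of fold sub-branches, not
  verified by a cusp normal form.
- The closed-form tree map component is exact only on the y-axis and at
  fixed points (where the burned-grass substitution holds); it is used
  nowhere else.
- `classify_region` near a bifurcation locus returns a `boundary` flag;
  the taxonomy is only meaningful for hyperbolic regimes.
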