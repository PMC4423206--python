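# Methods

`ecorange` studies eco-evolutionary feedbacks during range expansions: as a
population invades empty habitat, highly dispersive phenotypes accumulate at
the advancing front (spatial selection), and if dispersal trades off against
foraging ability this evolutionary change feeds back on the ecological
pattern — resource depletion, equilibrium densities and the shape of growth
curves. The package contains four scientific components: deterministic
growth models and their fitting pipeline, a stochastic individual-based
simulator, movement-path statistics, and synthetic-data generators that
emulate the statistical structure of protist-microcosm observations.

## Deterministic growth models

Consumer growth in a closed vessel is described either phenomenologically,

  dT/dt = r T (1 − T/K),

with the closed-form solution T(t) = K / (1 + (K/T0 − 1) e^{−rt}), or
mechanistically by a Rosenzweig–MacArthur consumer–resource system with a
type II functional response:

  dT/dt = e a N/(N + b) T − d_T T,
  dN/dt = r0 N (1 − N/K_N) − a N/(N + b) T.

Here `T` is consumer density (individuals ml⁻¹), `N` resource density
(bacterial-count units), `e` the assimilation coefficient (offspring per
resource unit), `a` the maximum intake rate, `b` the half-saturation
constant (1/b is the foraging efficiency) and `d_T` the death rate. Time is
in hours throughout. Resource-dependent fitness is the per-capita birth
minus death rate, g(N) = e a N/(N + b) − d_T.

Integration uses LSODA (`scipy.integrate.solve_ivp`, rtol 1e-8, atol
1e-10), the same family of solver used by standard ODE tooling in R; the
damped-oscillation regimes of this system are mildly stiff, where fixed
nonstiff Runge–Kutta schemes waste effort. Output states are clipped at
zero to remove tiny negative solver excursions. Correctness is checked
against an independent fixed-step RK4 integrator (dt = 1e-3 h) to 1e-4
relative accuracy.

## Fitting and model selection

Only consumer densities are observed, so the resource side of the
consumer–resource model is fixed (`r0 = 0.24 h⁻¹`, `K_N = 3.6e7`,
estimated externally from bacterial growth data), and the initial resource
density is pinned to `K_N`: fitting starts from freshly bacterized medium,
which sits at bacterial carrying capacity. The five consumer parameters
(e, a, b, d_T, T0) are estimated by Levenberg–Marquardt least squares on a
log10 scale (positivity plus scale-free steps). Because the least-squares
surface is multimodal, fitting is multi-started: a heuristic seed is read
off the curve shape (plateau height, early log-slope, time to plateau),
20 Latin-hypercube points spanning ±2 decades around it are ranked by
their residual sum of squares, and the best three are polished (bounds ±3
decades, evaluation budget 600 per start). The design is deterministic —
the Latin-hypercube seed is fixed — so a fit is a pure function of the
data. During optimisation the ODE is integrated with a hard step budget
(`odeint`, mxstep 8000); parameter regions whose dynamics exceed it (sharp
relaxation cycles far from any plausible fit) receive a flat penalty
residual. The returned residual sum of squares is recomputed with the
reference solver.

The logistic fit is self-starting in the manner of R's `SSlogis`: K from
the maximum density, T0 from the first positive density, r from the
log-density slope over the first three points.

Models are compared by AIC under the full Gaussian likelihood convention,

  AIC = n ln(2π) + n ln(RSS/n) + n + 2 (k + 1),

counting the estimated error variance as a parameter — the convention of
`AIC()` in R — so ΔAIC = AIC(logistic) − AIC(consumer–resource) values are
comparable across software. By default replicate curves are averaged at
shared time points before fitting (one fit per treatment); per-replicate
fitting is available but off by default.

**Identifiability.** A monotone saturating growth curve determines the net
growth rate e a N/(N+b) − d_T along its trajectory but cannot separate
d_T from (e, a, b): fits to such curves routinely return d_T near zero
with a compensating e·a at indistinguishable RSS. Consequently the fitted
fitness curve is reliable at moderate-to-high resource availability —
g(K_N) is pinned by the early slope — but its low-N tail (g(0) = −d_T) is
not. The end-to-end scenario study therefore scores fitness ordering at
N = K_N, the fresh-medium condition. Curves with a visible decline phase
(overshoot) identify d_T and, with it, the whole curve. Similarly, under
heavy noise e and a individually trade off; the compound birth scale e·a
is the quantity recovered robustly, and recovery is assessed on it.

## Individual-based simulator

A linear landscape of 100 patches holds a resource population per patch
with Beverton–Holt growth N′ = λ0 N / (1 + α N), α = (λ0 − 1)/K (K is the
fixed point; λ0 < 1 is rejected since α would be negative). Consumers are
individuals carrying heritable investment fractions
(f_d, f_a, f_{1/b}, f_else) that sum to one and map onto phenotypes

  d = min(1, f_d^θ d_max),  a_i = f_a^θ a_max,  (1/b)_i = f_{1/b}^θ invb_max,

with θ = 1 (linear) by default; θ ≠ 1 gives the convex/concave trade-off
variants. d_max ∈ {2, 3, 4} makes raw f_d·d_max exceed 1, which is
interpreted as a dispersal probability capped at one — selection pressure
on f_d persists below the cap. The fourth category f_else (investment in
unspecified activities) relaxes the strict two-way coupling of dispersal
and foraging; a four-way variant additionally evolves the assimilation
coefficient via f_e with e_i = f_e^θ e_max (simplex extended to five
values).

Each discrete, non-overlapping generation proceeds in fixed order:

1. **Resource growth** in every patch (plus optional external inflow,
   `inflow·K` per generation).
2. **Foraging**: within each patch consumers harvest sequentially in
   uniformly random order; each removes min(a_i N/(N + b_i), N − refuge·K)
   where N is the patch's current (already depleted) level. Mass balance
   is exact; a refuge floor (unconsumable biofilm fraction) is available
   and zero by default.
3. **Reproduction**: each adult leaves Poisson(e_i × intake) offspring and
   dies.
4. **Inheritance and mutation**: offspring copy the parent's investment
   fractions; each value independently mutates with probability
   p_mut = 0.001 by adding a Normal(0, 0.2) deviate, negatives are reset
   to zero, and the vector is renormalized to the simplex. (If a whole
   vector is clipped to zero — a measure-zero event — the mutation is
   re-drawn.)
5. **Natal dispersal**: each offspring attempts dispersal with probability
   d, survives the attempt with probability 1 − μ, and moves to one of its
   two neighbours with equal probability.

Runs start with 10 founders in each of the five leftmost (core) patches,
traits initialized uniformly at random and renormalized. During a
1,000-generation burn-in the core is wrapped to a ring (no boundary
artifacts) and a genetic algorithm settles on evolutionarily stable
trait combinations; afterwards the landscape opens with reflecting
boundaries (an individual stepping off an end is routed to the single
interior neighbour) and the expansion runs until the front reaches patch
99 or a 5,000-generation cap. Extinction is a flagged result, not an
exception. The founder count (10 per core patch) and the initial resource
level (K in every patch) are exposed in the configuration; both merely
set the burn-in transient.

Reference parameters: K = 50, λ0 = 4, μ = 0, d_max = 3, a_max = 0.03,
invb_max = 0.02, e = 700. The factorial experiment grid spans
λ0 ∈ {1.5, 2, 4, 6, 8, 10}, μ ∈ {0, 0.01, 0.1, 0.5}, d_max ∈ {2, 3, 4},
a_max ∈ {0.01, 0.02, 0.03}, invb_max ∈ {0.01, 0.02, 0.03},
e ∈ {700, 800, 900, 1000}, replicated (20 replicates by default) with
child seeds spawned from one root seed, so a sweep is reproducible from a
single integer.

Implementation: the population lives in flat numpy arrays (one row per
individual, ~10⁵–10⁶ individuals per generation at the reference
parameters); the sequential foraging pass is a numba-compiled kernel.
Identical configuration and seed give bit-identical trajectories.

**Core–margin contrasts.** With λ0 = 4 and efficient foragers, core
populations settle into pronounced consumer–resource oscillations, so a
core density read off a single generation reflects oscillation phase, not
the stable level (snapshots range over roughly 2×10³–1.6×10⁴ while the
margin sits near 9×10³). `core_margin_contrast` therefore compares the
margin's final mean density (patches ≥ 75) against the core's density
(patches ≤ 20) averaged over the recorded expansion generations. Trait
means change slowly and are compared as final snapshots.

## Movement statistics

A path is x/y positions at a uniform frame interval (default 1/25 s,
i.e. 25 frames s⁻¹; videos are 20 s, 500 frames). Velocity is the mean
per-step displacement divided by the frame interval (net displacement is
reported as a secondary statistic). Turning angles are signed heading
changes between consecutive non-zero steps; their circular s.d. is
√(−2 ln R̄) with R̄ the mean resultant length, floored at 1e-12 so a
uniform angle distribution yields a large finite value. Paths observed
for less than 4 s are filtered out before summarising, and summaries are
averaged per sample (population level). The statistics are coordinate-unit
agnostic (pixels or µm); both are invariant under rigid motions of the
coordinate frame.

## Synthetic data

The generators emulate what the analyses assume about microcosm data,
not any particular data set:

* **Growth curves** are sampled daily over 10 days with two extra early
  points (t = 0, 12, 24, 36, 48 h, then daily to 240 h), starting from a
  stock at equilibrium density (10⁴ ml⁻¹) diluted tenfold into fresh
  medium. Counting noise is Poisson on the number of individuals in a
  0.15 ml aliquot, divided by the aliquot volume — the error model of
  small-volume microscopy counts, which approaches Gaussian at high
  densities and becomes exact (noise-free) as the aliquot → ∞.
* **Paths** are correlated random walks with constant step length
  speed/fps and wrapped-normal turning increments.
* **The core-vs-margin scenario** draws two treatments from
  consumer–resource truths that differ only in foraging efficiency
  (core b = 2.0e7, margin b = 3.2e7, equal e = 2e-4, a = 1200,
  d_T = 0.1 h⁻¹), plus path sets with margin swim speed 30% above the
  core's (390 vs 300 µm s⁻¹, equal turning spread 0.45–0.6 rad). Both
  truths sit in the damped (stable-focus) regime of the
  consumer–resource system — the equilibrium resource level exceeds
  (K_N − b)/2 — so curves rise to a plateau with at most a mild
  overshoot rather than cycling, as microcosm growth curves do. Growth
  rates at carrying capacity are ~0.054 h⁻¹ (core) vs ~0.027 h⁻¹
  (margin). An equal-truth null variant gives both labels the same truth;
  any recovered ordering is then a coin flip by exchangeability, which
  calibrates the recovery study.

What the generators deliberately do not emulate: replicate-level random
effects and temporal autocorrelation of real microcosms, measurement
error in time, resource evolution, demographic stochasticity in the ODE
truths, and video-tracking artifacts (broken/merged tracks). Passing
recovery tests therefore show that the pipeline is correct and calibrated
under its own assumptions, not that those assumptions hold for any given
data set.

## Numerical choices and problem sizes

* ODE tolerances rtol 1e-8 / atol 1e-10 (reference solver); the fitting
  path integrates at rtol 1e-7 with a step budget, far below counting
  noise either way.
* AIC uses an RSS floor of 1e-300 only to keep the value finite for
  numerically perfect fits.
* The test suite runs 20 replicate simulations at the reference
  parameters and 50-replicate Monte-Carlo studies for recovery and model
  selection; `scripts/acceptance.py` recomputes the same quantities at 8
  simulation replicates, 20 fitting replicates and 15 scenarios per arm,
  sizes chosen to keep a full from-scratch rerun to a few minutes on one
  CPU while leaving Monte-Carlo error well inside the decision margins.
* Dispersal mortality applies only to individuals that attempt dispersal;
  failed survivors are removed (cost-as-mortality).
* Degenerate inputs: flat growth curves and series shorter than five
  points are fitting errors, not silent results; zero-length movement
  steps contribute no turning angle; a patch at its refuge floor yields
  zero intake; 1/b_i = 0 means an infinite half-saturation constant and
  zero intake, not a division error.

## Known limitations

* The simulator is deliberately minimal: no resource dispersal or
  evolution, no Allee effects, no density-dependent or plastic dispersal,
  no 2-D landscapes, and it is not fitted to data.
* The consumer–resource fit assumes N0 = K_N; if the medium were not
  fresh this would bias e·a downward.
* ΔAIC values computed on synthetic curves are not comparable to values
  obtained from any particular experimental data set; they demonstrate
  the calibration of the selection procedure only.
* With d_max > 1 the dispersal trait is effectively censored at
  probability one at the front, so "evolutionarily stable" front values
  of f_d depend on d_max only through the cap.
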