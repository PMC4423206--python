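# ecorange

Eco-evolutionary dynamics of range expansions, for researchers studying
how dispersal evolution at invasion fronts feeds back on ecological
pattern. When a population expands its range, highly dispersive
phenotypes accumulate at the advancing front (spatial selection). If
dispersal trades off against foraging ability, fronts evolve fast
dispersers that exploit resources prudently, while long-established
cores evolve efficient foragers that deplete resources — with visible
consequences for growth curves, equilibrium densities and spatial
density profiles.

The package provides:

* **Growth models and fitting** — logistic r–K growth and a
  Rosenzweig–MacArthur consumer–resource model with a type II
  functional response,

      dT/dt = e·a·N/(N+b)·T − d_T·T
      dN/dt = r0·N·(1−N/K_N) − a·N/(N+b)·T,

  fitted to consumer growth curves by multi-start Levenberg–Marquardt
  least squares (resource side fixed, e.g. r0 = 0.24 h⁻¹,
  K_N = 3.6×10⁷) and compared by AIC under the full Gaussian
  convention. Resource-dependent fitness g(N) = e·a·N/(N+b) − d_T is
  extracted from the fit.
* **An individual-based simulator** of consumers evolving investment
  fractions (f_d, f_a, f_{1/b}, f_else) on a simplex — mapping onto
  dispersal probability and functional-response parameters — while
  expanding through a linear landscape of 100 patches with
  Beverton–Holt resources, Poisson reproduction, mutation and natal
  dispersal.
* **Movement-path statistics** — velocity and circular s.d. of turning
  angles, √(−2 ln R̄), with a minimum-duration filter.
* **Synthetic-data generators** — growth curves with small-aliquot
  Poisson counting noise at a 10-day sampling design, correlated random
  walks at 25 frames/s, and a labelled core-vs-margin scenario for
  end-to-end pipeline checks.

See `docs/methods.md` for models, assumptions and numerical choices.

## Worked example

Generate a synthetic core-vs-margin scenario (six replicate growth
curves per treatment, movement paths), fit both growth models to the
replicate means, and summarise the paths:

```sh
ecorange synth scenario --seed 42 --replicates 6 --n-paths 20 --out demo
ecorange fit --input demo/growth_curves.csv --model both --out demo_fits
ecorange pathstats --input demo/paths_core.csv --out demo_stats
```

`demo_fits/fits.json` contains, per treatment, the fitted parameters,
RSS and AIC of both models. For seed 42 the consumer–resource model is
preferred for both treatments (ΔAIC = AIC_logistic − AIC_cr of 50.9 for
the core and 11.5 for the margin — the growth curves carry the signature
of resource depletion), and the fitted consumer parameters recover the
generating contrast: compound birth scale e·a = 0.243 h⁻¹ (core) vs
0.136 (margin), half-saturation b = 1.8×10⁷ (core) vs 5.2×10⁷ (margin),
i.e. the core treatment has the higher foraging efficiency 1/b and the
higher growth rate at any resource level near carrying capacity.
`demo_stats/path_stats.csv` lists per-path velocity (300 µm/s for the
core paths) and turning-angle circular s.d. (~0.59 rad).

Run one range-expansion simulation at the reference parameters
(a_max = 0.03, e = 700, 1/b_max = 0.02, λ0 = 4, K = 50, μ = 0,
d_max = 3) and inspect the spatial profile:

```python
from ecorange import SimConfig, run_simulation
from ecorange.simulator import core_margin_contrast

res = run_simulation(SimConfig(seed=7), record_every=5)
print(res.completed, res.generations)   # True 108
print(core_margin_contrast(res))
```

A typical run completes the expansion in ~110 generations; the contrast
dictionary shows the three signatures of spatial selection with a
dispersal–foraging trade-off: margin density above the core's temporal
mean, margin mean dispersal ~0.5 vs core ~0.05–0.1, and margin foraging
efficiency ~0.0075 vs core ~0.009.

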