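# ratchet

Muller's ratchet with overlapping generations: stochastic simulators of the
full multi-class ratchet (Moran, Wright–Fisher, diffusion limit), an exactly
solvable two-class reduction, and WKB rare-event analytics for the click rate
and the quasi-stationary distribution of the fittest class.

## The problem

In a finite asexual population of size *N*, deleterious mutations arrive at
genomic rate *U* per generation and each costs a factor (1−*s*) of fitness,
so an individual with *k* mutations grows at rate ∝ (1−*s*)^*k*. Without
back mutation or recombination, the class of least-loaded individuals can be
lost by a chance fluctuation — a **click** of the ratchet — after which the
minimum load has increased irreversibly. The mean time *T* between clicks
(the inverse ratchet rate) is the central quantity: it controls the speed of
genomic degeneration of Y chromosomes, mitochondria and asexual lineages.

At mutation–selection balance an infinite population carries a Poisson
profile with mean λ = *U*/*s* over the load classes, so the fittest class
holds *N*·e^{−λ} individuals. In the *rare-clicking regime* the population
relaxes to a metastable state between clicks and extinction of the fittest
class is a rare, large fluctuation — exponentially sensitive to *N*, and
outside the comfort zone of diffusion approximations.

## What the package computes

- **Full-model simulators** (`moran`, `wright_fisher`, `diffusion`):
  overlapping-generation Moran birth–death dynamics, Haigh's multinomial
  Wright–Fisher resampling, and Euler–Maruyama integration of the
  class-frequency SDE with genetic-drift noise. One Moran generation is *N*
  elementary steps; Wright–Fisher at *N*/2 matches Moran at *N* (the
  factor-two diffusion-constant correction). JIT-compiled kernels simulate
  hundreds of clicks per second at desk scale.
- **Two-class reduction** (`params.map_parameters`, `twoclass`): the fittest
  class against a merged mutated background with effective parameters
  *u* = 1−e^{−*U*} and *s*_eff = *u*/(1−e^{−λ}), fixed by matching the
  equilibrium mean fitness of the population and of the mutated individuals.
  The fittest-class count then performs a one-dimensional birth–death chain
  whose mean click time from *n*₀ = *N*·e^{−λ} individuals,

      T = (1/N) · Σ_{k=1..n0} Σ_{j=k..N} (1/t₋(j)) Π_{i=k..j−1} t₊(i)/t₋(i),

  is evaluated exactly in the log domain, cross-checked against an
  exact-rational linear solve of the first-step equations, the dominant
  eigenpair of the master-equation operator, and Monte Carlo.
- **WKB (eikonal) analytics** (`wkb`): writing the quasi-stationary
  distribution as π(x) ~ e^{−N·S(x)} with the action
  S(x) = ∫ ln[t₋/t₊] dξ (closed form), the package provides the
  leading-order and 1/N-corrected QSD, the boundary-matched mean time to
  extinction, the large-*Ns* closed form

      T ≈ (1/s_eff) √(2π/(N s_eff λ₀)) (1−λ₀)^{−2} · exp{N s_eff (1−λ₀+λ₀ ln λ₀)},

  and its decomposition into prefactor and exponent — including the analytic,
  λ₀-dependent replacement of the classical "Haigh factor".

## Worked example

```python
import ratchet as rt

full = rt.FullParams(N=100, U=0.1, s=0.2)       # lam = 0.5
tc = rt.map_parameters(full)
print(f"u={tc.u:.5f} s_eff={tc.s_eff:.5f} x*={tc.x_star:.4f}")

mte = rt.exact_mfpt(rt.build_rates(tc))
print(f"two-class exact mean click time: {mte:.1f} generations")

sim = rt.first_click_times(full, 500, seed=11)
print(f"full Moran ratchet:              {sim.mean:.1f} +- {sim.se:.1f} generations")

res = rt.wkb_mte(rt.TwoClassParams(N=300, u=0.03, s_eff=0.1))
print(f"WKB mean time to extinction (N=300, lam0=0.3): {res.mte:.3g} generations")
```

prints

```
u=0.09516 s_eff=0.24186 x*=0.6065
two-class exact mean click time: 7437.7 generations
full Moran ratchet:              14422.3 +- 660.0 generations
WKB mean time to extinction (N=300, lam0=0.3): 7.8e+05 generations
```

The mapped two-class model reproduces the mutation rate out of the fittest
class and places its equilibrium at x* = e^{−λ} exactly; its exact solution
and the WKB analytics agree to a fraction of a percent in log-time. The full
ratchet clicks more slowly than the reduced model by a λ₀-dependent factor
(here ≈1.9) because the surviving lineages' mutant background is biased
toward higher load than the equilibrium profile assumed by the mapping — see
`docs/methods.md` for the quantitative picture and validity limits.

## Command line

```
ratchet simulate-moran --n 100 --u 0.1 --s 0.2 --replicates 500 --seed 1 --out out/
ratchet exact-mfpt     --n 100 --u 0.03 --s-eff 0.1
ratchet wkb            --n 300 --u 0.03 --s-eff 0.1 --order prefactor
ratchet compare        --config grid.yaml --out out/
```

Each command writes delimited text tables plus a JSON manifest with all
derived quantities for provenance.

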