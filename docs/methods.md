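# Methods

## Models

**Full ratchet.** A haploid asexual population of fixed size N is organised
into classes by mutation count k; class-k individuals have multiplicative
fitness (1−s)^k. Mutations are irreversible and arrive on offspring as
Poisson(U) counts (a `bernoulli` switch is provided for sensitivity checks).
Three interchangeable dynamics are implemented:

- *Moran* (overlapping generations): each elementary step one parent is
  drawn proportionally to class-weighted fitness, its offspring mutates,
  and one uniformly chosen individual (possibly the parent, never the
  newborn) dies. One generation = N steps.
- *Wright–Fisher* (non-overlapping): each generation is one multinomial
  draw of size N from the fitness-weighted, mutation-convolved parent
  frequencies.
- *Diffusion limit*: the class-frequency SDE with drift
  −s(k−k̄)x_k + U(x_{k−1}−x_k) and independent genetic-drift noise of
  variance x_k/N_e per class per generation, integrated by Euler–Maruyama.

A click is the emptying of the least-loaded class; the class window
(K = max(10λ+20, 40) classes above the current minimum, overflow folded into
the edge class) is re-indexed after each click. Click times are reported in
generations.

**Two-class reduction.** The fittest class (frequency x) against a single
merged background of relative fitness 1−s_eff, with mutation rate u out of
the fittest class. The count n = Nx performs a lazy birth–death chain with
per-step probabilities

    t₊(n) = [n/(n+(1−s_eff)(N−n))] (1−u) (N−n)/N
    t₋(n) = [((1−s_eff)(N−n) + u n)/(n+(1−s_eff)(N−n))] (n/N),

absorbing at n = 0, reflecting at n = N, deterministic fixed point
x* = 1 − u/s_eff (requires u < s_eff).

**Parameter mapping.** u and s_eff are fixed by three conditions evaluated
at the infinite-N equilibria: equal out-rate from the fittest class
(u = 1 − e^{−U}, the Poisson probability of at least one new mutation),
equal population mean fitness, and equal mean fitness of mutated
individuals. Together these give s_eff = u/(1−e^{−λ}), λ₀ ≡ u/s_eff =
1 − e^{−λ}, hence x* = e^{−λ}: the reduced model holds N e^{−λ} fittest
individuals, as the full model does. A `linear` convention (u = U) is
available; λ₀ and x* are convention-independent. When N e^{−λ} < 1 the
reduction is meaningless and a `RegimeWarning` is attached.

## Exact solutions of the reduced chain

- *Mean first-passage time*: the classical nested-product formula, summed
  in the log domain (suffix log-sum-exp), overflow-free for any N. Initial
  condition n₀ = round(N x*) throughout.
- *Independent oracle*: the first-step linear system solved by Thomas
  elimination in exact rational arithmetic (`fractions.Fraction` on the
  binary transition probabilities). The float LAPACK path is also provided,
  but in deep-barrier corners (MFPT ≳ 1e10 generations) the system's
  condition number is of the order of the MFPT itself and double precision
  saturates near 1e-5 relative error; the rational solve certifies the
  product formula to ~1e-14.
- *Quasi-stationary distribution and decay rate*: the birth–death operator
  restricted to {1..N} is symmetrised by the standard similarity transform
  and the dominant eigenpair obtained with a tridiagonal eigensolver; the
  left Perron vector is recovered in the log domain (the similarity weights
  span e^{±N·S}). Rate = (1−eigenvalue)·N per generation; the flux identity
  rate = N·t₋(1)·q₁ is verified to 1e-6 relative.
- *Master equation*: explicit stepping with the absorbing state carried
  along, conserving total probability to <1e-10 over 1e6 steps; the
  late-time survival decay reproduces the eigen rate to <2%.

## WKB approximation

With π(n) ∝ exp(−N S(x)), x = n/N, the stationary master equation gives to
leading order S'(x) = ln[t₋(x)/t₊(x)], integrated in closed form
(logarithms of the linear factors of the rates; the u+s_eff = 1 degenerate
slope is handled separately and checked against quadrature at 1e-10). S is
minimal at x*, S(x*) = 0.

- *Leading-order QSD*: exp(−N S), normalised with the Gaussian-peak
  constant √(S''(x*)/2πN).
- *Prefactor QSD*: the 1/N correction contributes 1/√(t₊t₋); this matches
  the discrete product solution including its trapezoidal (Euler–Maclaurin)
  correction and is the form compared with the eigen oracle (total
  variation ~1e-4 at N=300, λ₀=0.3, s_eff=0.1). The finite-N prefactor
  skews the mode upward by O(1/s_eff) individuals relative to N x* — the
  eigen oracle shows the same shift.
- *Mean time to extinction*: the WKB form is invalid near the absorbing
  boundary, so the MTE factorises into a bulk Laplace integral over the
  metastable peak, √(2πN/S''(x*)) e^{N S(1/N) − S'(1/N)/2}/t₋(x*), times
  the exact discrete boundary-layer sum Σ_k Π_{i<k} t₋(i)/t₊(i) (a
  geometric-like series with ratio → (1−s_eff)/(1−u); summed to numerical
  convergence, never beyond the fixed point). Accuracy against the exact
  MFPT: 0.2% in log-time at (N=300, λ₀=0.3, s_eff=0.1), improving with N.
  The purely leading-order rate (flux of the Gaussian-normalised leading
  QSD) is exponentially accurate only: its ratio to the exact rate drifts
  with N while the log-rates converge; it is reported as a diagnostic.
- *Simplified closed form*: expanding at fixed (N s_eff, λ₀) to leading
  order in small s_eff,

      MTE = (1/s_eff) √(2π/(N s_eff λ₀)) (1−λ₀)^{−2} exp{N s_eff g(λ₀)},
      g(λ₀) = 1 − λ₀ + λ₀ ln λ₀.

  The deviation from the boundary-matched expression is O(s_eff) at fixed
  N s_eff (measured: 43% at s_eff = 0.1, 3.7% at s_eff = 0.0025, both at
  N s_eff = 30), so the form is quantitative only near the diffusion scale;
  it always carries the correct exponent and the 1/s_eff time scaling. The
  exponent coefficient per fittest individual, g(λ₀)/(1−λ₀), is the
  analytic replacement of the classical ad hoc "Haigh factor": it decreases
  with λ₀, passes through the historical 0.5–0.6 range near λ₀ ≈ 0.25, and
  tends to 1 as λ₀ → 0.

Every WKB result carries machine-checkable validity flags (N·S(1/N),
N s_eff x*, distance of x* from the boundary in units of 2/√N); out-of-regime
requests warn and still return.

## Numerical and design choices

- Simulation kernels are JIT-compiled (numba) with numba's own seeded RNG;
  a plain-numpy single-step reference defines the semantics and the kernels
  are validated against it distributionally, and — restricted to a
  two-class window — against the exact MFPT. All entry points are
  deterministic given a seed.
- SDE: noise amplitude √(x_k/N_e) with N_e = N/2, matching the Moran
  generation convention (twice the Wright–Fisher variance), so
  diffusion(N), Moran(N) and Wright–Fisher(N/2) are directly comparable.
  Uncorrelated per-class noise followed by clamping at 0 and simplex
  renormalisation reproduces the multinomial covariance to leading order.
  Default dt = 0.01/max(s·K, U, 1), adaptively halved on undershoot;
  absorption threshold x_abs = 1/(2N) (half an individual). Halving dt
  leaves click times statistically unchanged (no resolvable bias down to
  dt = 5e-4 at 3000 replicates).
- Initial conditions: largest-remainder rounding of the N·Poisson(λ)
  profile (counts sum to N exactly); frequencies analogous for the SDE.
- Click-time studies use independent replicates of the first click from
  the equilibrium profile; successive-click sampling along one trajectory
  is also provided and gives statistically indistinguishable means in the
  rare-clicking regime (measured ratio of protocols ≈ 1.0 at λ = 0.5, 0.8).

## What the comparisons show — and their limits

- The three full-model formulations agree: mean click times of Moran(N),
  Wright–Fisher(N/2) and diffusion(N) coincide within sampling error
  (≤1.5 combined SE at 500 clicks) across slow (metastable, MTE ≈ 90
  relaxation times) and fast regimes, for points near the diffusion scale
  (s·λ ≲ 0.1, N e^{−λ} ≳ 30). Away from it the microscopic models remain
  mutually consistent but the SDE clicks measurably faster once the
  fittest class holds only a few individuals (no discreteness floor) —
  e.g. ~20% at N e^{−λ} ≈ 5.
- The two-class reduction reproduces the full ratchet's quasi-stationary
  *distribution* closely (total variation 0.04–0.06 against 5000-replicate
  histograms for λ₀ ≤ 0.4), but its mean click time is systematically
  optimistic: the full ratchet clicks slower by a factor growing from
  ≈1.2 (λ₀ ≈ 0.18) to ≈1.9 (λ₀ ≳ 0.4), robustly across s_eff at fixed λ₀
  and barrier height. The equilibrium-based mapping fixes the background
  fitness at its unconditional equilibrium value, whereas conditioning on
  fittest-class survival biases the background toward higher load (fitter
  backgrounds are precisely the ones that drive class 0 extinct), which
  stabilises the fittest class — an effect absent from any static two-class
  model and growing with background heterogeneity λ₀. On the logarithmic
  scale on which click times are usually compared the discrepancy is a few
  percent of ln T; on a linear scale it is not small, and tests that demand
  linear-scale agreement of the two models fail by design here.
- The synthetic study conditions are desk scale (N ≤ 500 for simulations,
  hundreds of clicks per point, ≥3000 histogram replicates). They probe
  exactness of the reduced-model machinery, mutual consistency of the
  simulators, and the WKB asymptotics within their stated regimes; they do
  not probe biological complications (epistasis, back mutation,
  recombination, variable N), which are outside the model class.
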