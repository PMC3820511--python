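"""Haigh's Wright-Fisher formulation of Muller's ratchet.

Non-overlapping generations: each generation the whole population is replaced
by one multinomial draw of size N whose class probabilities are the current
fitness-weighted class frequencies convolved with the Poisson(U) mutation
kernel,

    p_k  propto  sum_j  [ x_j (1-s)^j / wbar ] * e^{-U} U^{k-j} / (k-j)!.

One Wright-Fisher generation equals one Moran generation (N Moran steps); in
the diffusion limit the two models differ by a factor of two in the genetic
drift variance, so Wright-Fisher at population size N/2 matches Moran at N —
the basis of the cross-model comparisons.

The deterministic (infinite-N) limit of the resampling is the classical
mutation-selection recursion, whose fixed point is the Poisson(lam) profile;
both the expectation identity and the fixed point are exercised in the tests.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy import stats

from .moran import PopulationState, class_window, initial_state
from .params import FullParams
from .results import ClickTimeSample


def mutation_pmf(U: float, m_max: int | None = None) -> np.ndarray:
    """Poisson(U) offspring-mutation-count probabilities, the tail folded
    into the last entry so the vector sums to one exactly."""
    if m_max is None:
        m_max = max(8, int(3 * U + 8))
    pm = stats.poisson.pmf(np.arange(m_max + 1), U)
    pm[-1] += stats.poisson.sf(m_max, U)
    return pm


def selection_mutation_probs(freqs: np.ndarray, params: FullParams) -> np.ndarray:
    """Expected next-generation class probabilities (the deterministic
    recursion): fitness weighting followed by mutation convolution, overflow
    folded into the last window class."""
    K = len(freqs)
    w = freqs * (1.0 - params.s) ** np.arange(K)
    w = w / w.sum()
    pm = mutation_pmf(params.U)
    q = np.zeros(K)
    for j, pj in enumerate(pm):
        if pj == 0.0:
            continue
        if j == 0:
            q += pj * w
        else:
            q[j:] += pj * w[: K - j]
    # fold the overflow beyond the window edge into the last class; guard
    # against a rounding ulp pushing the correction negative
    deficit = 1.0 - q.sum()
    if deficit > 0.0:
        q[-1] += deficit
    np.clip(q, 0.0, None, out=q)
    return q / q.sum()


def haigh_recursion_fixed_point(
    params: FullParams,
    K: int | None = None,
    tol: float = 1e-12,
    max_iter: int = 100000,
) -> tuple[np.ndarray, int]:
    """Iterate the deterministic mutation-selection recursion to its fixed
    point (the Poisson(lam) profile); returns (frequencies, iterations)."""
    if K is None:
        K = class_window(params)
    x = np.full(K, 1.0 / K)
    for it in range(1, max_iter + 1):
        x_new = selection_mutation_probs(x, params)
        if np.max(np.abs(x_new - x)) < tol:
            return x_new, it
        x = x_new
    return x, max_iter


def wf_step(
    state: PopulationState, params: FullParams, rng: np.random.Generator
) -> PopulationState:
    """One Wright-Fisher generation: a single multinomial resampling of the
    fitness-weighted, mutation-convolved parent frequencies."""
    q = selection_mutation_probs(state.counts / state.N, params)
    counts = rng.multinomial(state.N, q).astype(np.int64)
    new = PopulationState(counts=counts, k_min=state.k_min, t_steps=state.t_steps + 1)
    if new.counts[0] == 0:
        shift = int(np.argmax(new.counts > 0))
        new.counts = np.concatenate([new.counts[shift:], np.zeros(shift, np.int64)])
        new.k_min += shift
    return new


@njit(cache=True)
def _wf_first_click_kernel(counts0, fit, pm, N, reps, max_gens, seed):
    """First click time (generations) per replicate; -1 marks censoring.

    Multinomial sampling is performed as a chain of conditional binomials,
    which is exact and robust to floating-point renormalisation.
    """
    np.random.seed(seed)
    K = counts0.shape[0]
    M = pm.shape[0]
    out = np.empty(reps)
    w = np.empty(K)
    q = np.empty(K)
    counts = np.empty(K, dtype=np.int64)
    for r in range(reps):
        for j in range(K):
            counts[j] = counts0[j]
        t = -1.0
        for g in range(1, max_gens + 1):
            tot = 0.0
            for j in range(K):
                w[j] = counts[j] * fit[j]
                tot += w[j]
            for j in range(K):
                w[j] /= tot
            for k in range(K):
                acc = 0.0
                jmax = k if k < M else M - 1
                for m in range(jmax + 1):
                    acc += w[k - m] * pm[m]
                q[k] = acc
            # fold the overflow into the edge class
            ssum = 0.0
            for k in range(K):
                ssum += q[k]
            q[K - 1] += 1.0 - ssum
            # multinomial via conditional binomials
            remaining = N
            prem = 1.0
            for k in range(K):
                if remaining <= 0:
                    counts[k] = 0
                    continue
                if k == K - 1:
                    counts[k] = remaining
                    break
                pk = q[k] / prem
                if pk >= 1.0:
                    counts[k] = remaining
                    remaining = 0
                    prem = 0.0
                    continue
                if pk < 0.0:
                    pk = 0.0
                draw = np.random.binomial(remaining, pk)
                counts[k] = draw
                remaining -= draw
                prem -= q[k]
            if counts[0] == 0:
                t = g
                break
        out[r] = t
    return out


def wf_click_times(
    params: FullParams,
    reps: int,
    seed: int = 0,
    init: str = "haigh_equilibrium",
    max_generations: int | None = None,
) -> ClickTimeSample:
    """Time to first click per replicate under Wright-Fisher resampling
    (one WF generation = one time unit)."""
    state = initial_state(params, init=init)
    K = len(state.counts)
    fit = (1.0 - params.s) ** np.arange(K)
    pm = mutation_pmf(params.U)
    if max_generations is None:
        max_generations = 100000
    gens = _wf_first_click_kernel(
        state.counts, fit, pm, params.N, reps, int(max_generations), seed
    )
    ok = gens > 0
    return ClickTimeSample(
        times=gens[ok],
        model="wright_fisher",
        seed=seed,
        params=params,
        censored=int((~ok).sum()),
        censored_time=float(max_generations),
        meta={"init": init},
    )


def halved_population(params: FullParams) -> FullParams:
    """The Wright-Fisher counterpart of a Moran population: floor(N/2)
    individuals (the factor-two diffusion-constant correction).  For odd N
    the O(1/N) mismatch is recorded by the caller's manifest."""
    return FullParams(N=max(params.N // 2, 1), U=params.U, s=params.s)
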