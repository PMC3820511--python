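"""Full multi-class Moran model of Muller's ratchet (overlapping generations).

Individuals are grouped by their number of deleterious mutations; class k has
fitness ``(1-s)**k``.  At each elementary step one individual is chosen to
reproduce, with probability proportional to the fitness-weighted class
occupancy; its offspring acquires a Poisson(U)-distributed number of new
mutations (mutation is divorced from the birth/death drawing); and one
individual — possibly the reproducer — is removed uniformly at random.  The
population size N is conserved exactly.  One generation is N steps.

A click occurs when the least-loaded class empties; the class window is then
re-indexed so that index 0 is again the fittest occupied class.  The window
holds K classes above the current minimum; mutation overflow beyond the
window is folded into the last class (the occupancy there is negligible for
every regime of interest).

The simulation kernels are JIT-compiled; a plain-numpy single-step reference
(:func:`moran_step`) defines the semantics and the kernels are validated
against it distributionally in the tests.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .params import FullParams, haigh_steady_state, map_parameters
from .results import ClickTimeSample, QSDTable
from dataclasses import dataclass


@dataclass
class PopulationState:
    """Integer class occupancies over the current window.

    ``counts[j]`` is the number of individuals carrying ``k_min + j``
    mutations; ``sum(counts) == N`` always, and ``counts[0] >= 1`` between
    clicks by definition of ``k_min``.
    """

    counts: np.ndarray
    k_min: int = 0
    t_steps: int = 0

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    @property
    def n0(self) -> int:
        """Occupancy of the least-loaded class."""
        return int(self.counts[0])


def class_window(params: FullParams) -> int:
    """Number of classes kept above the least-loaded one."""
    return int(min(max(10.0 * params.lam + 20.0, 40.0), 400.0))


def fitness_weights(params: FullParams, K: int) -> np.ndarray:
    """Relative fitness (1-s)**j of window class j; the common factor
    (1-s)**k_min cancels from every choice probability."""
    return (1.0 - params.s) ** np.arange(K)


def initial_state(
    params: FullParams, init: str = "haigh_equilibrium", K: int | None = None
) -> PopulationState:
    """Deterministic initial occupancy.

    ``haigh_equilibrium`` distributes N individuals over the Poisson(lam)
    equilibrium profile by largest-remainder rounding (counts sum to N
    exactly); ``monomorphic`` puts everyone in class 0.
    """
    if K is None:
        K = class_window(params)
    if init == "monomorphic":
        counts = np.zeros(K, dtype=np.int64)
        counts[0] = params.N
        return PopulationState(counts=counts)
    if init != "haigh_equilibrium":
        raise ValueError(f"unknown init {init!r}")
    pi, tail = haigh_steady_state(params.lam, K - 1)
    target = params.N * (pi + 0.0)
    target[-1] += params.N * tail
    counts = np.floor(target).astype(np.int64)
    remainder = target - counts
    short = params.N - int(counts.sum())
    if short > 0:
        top = np.argsort(remainder)[::-1][:short]
        counts[top] += 1
    return PopulationState(counts=counts)


def moran_step(
    state: PopulationState,
    params: FullParams,
    rng: np.random.Generator,
    mutation_model: str = "poisson",
) -> PopulationState:
    """One elementary birth-death step (reference implementation).

    Returns a new state; total count is conserved by construction.  The
    bulk kernels reproduce exactly these semantics.
    """
    counts = state.counts.copy()
    K = len(counts)
    w = counts * fitness_weights(params, K)
    birth = rng.choice(K, p=w / w.sum())
    death = rng.choice(K, p=counts / counts.sum())
    if mutation_model == "poisson":
        m = rng.poisson(params.U)
    elif mutation_model == "bernoulli":
        m = int(rng.random() < params.U)
    else:
        raise ValueError(f"unknown mutation_model {mutation_model!r}")
    counts[min(birth + m, K - 1)] += 1
    counts[death] -= 1
    new = PopulationState(counts=counts, k_min=state.k_min, t_steps=state.t_steps + 1)
    if new.counts[0] == 0:
        shift = int(np.argmax(new.counts > 0))
        new.counts = np.concatenate([new.counts[shift:], np.zeros(shift, np.int64)])
        new.k_min += shift
    return new


# ----------------------------------------------------------------------
# JIT kernels
# ----------------------------------------------------------------------

@njit(cache=True)
def _one_step(counts, fit, N, U, K, hi, bernoulli):
    """One elementary birth-death step in place; returns the new top of the
    occupied class range.  Scans only classes [0, hi)."""
    # birth: fitness-weighted class choice
    tot = 0.0
    for j in range(hi):
        tot += counts[j] * fit[j]
    rb = np.random.random() * tot
    acc = 0.0
    b = hi - 1
    for j in range(hi):
        acc += counts[j] * fit[j]
        if rb < acc:
            b = j
            break
    # mutation, divorced from the birth/death drawing
    if bernoulli:
        m = 1 if np.random.random() < U else 0
    else:
        m = np.random.poisson(U)
    kb = b + m
    if kb >= K:
        kb = K - 1
    # death: uniform over the N current individuals
    rd = np.random.random() * N
    acc = 0.0
    d = hi - 1
    for j in range(hi):
        acc += counts[j]
        if rd < acc:
            d = j
            break
    counts[kb] += 1
    counts[d] -= 1
    if kb >= hi:
        hi = kb + 1
    while hi > 1 and counts[hi - 1] == 0:
        hi -= 1
    return hi


@njit(cache=True)
def _first_click_kernel(counts0, fit, N, U, reps, max_steps, seed, bernoulli):
    """First click time (steps) per replicate; -1 marks a censored run."""
    np.random.seed(seed)
    K = counts0.shape[0]
    out = np.empty(reps)
    hi0 = K
    while hi0 > 1 and counts0[hi0 - 1] == 0:
        hi0 -= 1
    for r in range(reps):
        counts = counts0.copy()
        hi = hi0
        t = -1.0
        step = 0
        while step < max_steps:
            step += 1
            hi = _one_step(counts, fit, N, U, K, hi, bernoulli)
            if counts[0] == 0:
                t = step
                break
        out[r] = t
    return out


@njit(cache=True)
def _shift_window(counts, K, hi):
    """Re-index after a click so index 0 is the fittest occupied class;
    returns (shift, new_hi)."""
    sh = 0
    while sh < K and counts[sh] == 0:
        sh += 1
    for j in range(K - sh):
        counts[j] = counts[j + sh]
    for j in range(K - sh, K):
        counts[j] = 0
    hi = hi - sh
    if hi < 1:
        hi = 1
    return sh, hi


@njit(cache=True)
def _successive_clicks_kernel(counts0, fit, N, U, n_clicks, max_steps, seed, bernoulli):
    """Click times (steps, from t=0) of one trajectory, re-indexing the
    window after each click."""
    np.random.seed(seed)
    K = counts0.shape[0]
    counts = counts0.copy()
    hi = K
    while hi > 1 and counts[hi - 1] == 0:
        hi -= 1
    times = np.empty(n_clicks)
    found = 0
    step = 0
    while step < max_steps and found < n_clicks:
        step += 1
        hi = _one_step(counts, fit, N, U, K, hi, bernoulli)
        if counts[0] == 0:
            times[found] = step
            found += 1
            _, hi = _shift_window(counts, K, hi)
    return times[:found], step


@njit(cache=True)
def _sample_n0_kernel(counts0, fit, N, U, reps, sample_steps, seed, bernoulli):
    """Fittest-class occupancy after sample_steps steps, per replicate;
    -1 marks replicates that clicked before the sampling time."""
    np.random.seed(seed)
    K = counts0.shape[0]
    out = np.empty(reps, dtype=np.int64)
    hi0 = K
    while hi0 > 1 and counts0[hi0 - 1] == 0:
        hi0 -= 1
    for r in range(reps):
        counts = counts0.copy()
        hi = hi0
        clicked = False
        for step in range(sample_steps):
            hi = _one_step(counts, fit, N, U, K, hi, bernoulli)
            if counts[0] == 0:
                clicked = True
                break
        out[r] = -1 if clicked else counts[0]
    return out


@njit(cache=True)
def _occupancy_kernel(counts0, fit, N, U, total_steps, burn_steps, seed):
    """Time-averaged fittest-class occupancy after a burn-in, following the
    trajectory through clicks (window re-indexed)."""
    np.random.seed(seed)
    K = counts0.shape[0]
    counts = counts0.copy()
    hi = K
    while hi > 1 and counts[hi - 1] == 0:
        hi -= 1
    acc_n0 = 0.0
    n_acc = 0
    for step in range(total_steps):
        hi = _one_step(counts, fit, N, U, K, hi, False)
        if counts[0] == 0:
            _, hi = _shift_window(counts, K, hi)
        if step >= burn_steps:
            acc_n0 += counts[0]
            n_acc += 1
    return acc_n0 / n_acc


# ----------------------------------------------------------------------
# public API
# ----------------------------------------------------------------------

def first_click_times(
    params: FullParams,
    reps: int,
    seed: int = 0,
    init: str = "haigh_equilibrium",
    max_steps: float | None = None,
    mutation_model: str = "poisson",
) -> ClickTimeSample:
    """Time to the first click, one value per independent replicate.

    Replicates that do not click within ``max_steps`` elementary steps are
    censored (their count and the censoring time are carried on the sample,
    no exception is raised), so rare-click regimes degrade gracefully.
    """
    state = initial_state(params, init=init)
    fit = fitness_weights(params, len(state.counts))
    if max_steps is None:
        max_steps = 1e5 * params.N  # per-replicate budget: 1e5 generations
    steps = _first_click_kernel(
        state.counts,
        fit,
        params.N,
        params.U,
        reps,
        float(max_steps),
        seed,
        mutation_model == "bernoulli",
    )
    ok = steps > 0
    return ClickTimeSample(
        times=steps[ok] / params.N,
        model="moran",
        seed=seed,
        params=params,
        censored=int((~ok).sum()),
        censored_time=float(max_steps) / params.N,
        meta={"init": init, "mutation_model": mutation_model},
    )


def run_until_clicks(
    params: FullParams,
    n_clicks: int,
    seed: int = 0,
    init: str = "haigh_equilibrium",
    max_steps: float | None = None,
    mutation_model: str = "poisson",
) -> ClickTimeSample:
    """Follow one trajectory until ``n_clicks`` clicks, re-indexing the
    class window after each; returns the click times from t=0 in
    generations (inter-click intervals are their differences, kept in
    ``meta``)."""
    if n_clicks < 1:
        raise ValueError("n_clicks must be >= 1")
    state = initial_state(params, init=init)
    fit = fitness_weights(params, len(state.counts))
    if max_steps is None:
        max_steps = 5e4 * params.N * n_clicks
    times, last_step = _successive_clicks_kernel(
        state.counts,
        fit,
        params.N,
        params.U,
        n_clicks,
        float(max_steps),
        seed,
        mutation_model == "bernoulli",
    )
    times = times / params.N
    censored = n_clicks - len(times)
    return ClickTimeSample(
        times=times,
        model="moran",
        seed=seed,
        params=params,
        censored=censored,
        censored_time=last_step / params.N,
        meta={
            "init": init,
            "mutation_model": mutation_model,
            "inter_click": np.diff(np.concatenate([[0.0], times])),
        },
    )


def mean_fittest_occupancy(
    params: FullParams,
    total_generations: float,
    seed: int = 0,
    burn_fraction: float = 0.1,
) -> float:
    """Time-averaged occupancy of the least-loaded class (after burn-in),
    following the trajectory through clicks; compares against the Haigh
    equilibrium value N exp(-lam) in the rare-click regime."""
    state = initial_state(params)
    fit = fitness_weights(params, len(state.counts))
    total = int(total_generations * params.N)
    return _occupancy_kernel(
        state.counts, fit, params.N, params.U, total, int(total * burn_fraction), seed
    )


def sample_fittest_histogram(
    params: FullParams,
    replicates: int = 5000,
    sample_fraction: float = 0.1,
    seed: int = 0,
    mean_click_time: float | None = None,
) -> QSDTable:
    """Quasi-stationary histogram of the fittest-class occupancy.

    Each replicate starts at the Haigh equilibrium profile and evolves for
    ``sample_fraction`` of the mean click time — long enough to relax to
    the metastable state, short enough that few replicates have clicked —
    at which point its fittest-class occupancy is recorded.  Replicates
    that already clicked are excluded (their number is reported in flags).

    The mean click time is estimated, unless supplied, from the exact MFPT
    of the mapped two-class model (deterministic, no extra simulation).
    """
    if not (0.0 < sample_fraction < 1.0):
        raise ValueError("sample_fraction must lie in (0, 1)")
    if replicates < 100:
        raise ValueError("need at least 100 replicates for a histogram")
    if mean_click_time is None:
        from .twoclass import build_rates, exact_mfpt

        mean_click_time = exact_mfpt(build_rates(map_parameters(params)))
    sample_steps = int(round(sample_fraction * mean_click_time * params.N))
    state = initial_state(params)
    fit = fitness_weights(params, len(state.counts))
    n0 = _sample_n0_kernel(
        state.counts, fit, params.N, params.U, replicates, sample_steps, seed, False
    )
    clicked = int((n0 < 0).sum())
    if clicked > 0.5 * replicates:
        raise RuntimeError(
            f"{clicked}/{replicates} replicates clicked before the sampling "
            f"time; sample_fraction={sample_fraction} is too large for this regime"
        )
    kept = n0[n0 > 0]
    support = np.arange(1, params.N + 1)
    mass = np.bincount(kept, minlength=params.N + 1)[1:].astype(float)
    mass /= mass.sum()
    return QSDTable(
        support=support,
        mass=mass,
        source="simulation",
        flags={
            "replicates": replicates,
            "clicked_before_sampling": clicked,
            "sample_time_generations": sample_steps / params.N,
            "mean_click_time_estimate": mean_click_time,
        },
    )
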