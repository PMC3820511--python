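"""Mesoscopic diffusion limit of the ratchet: coupled SDEs for the class
frequencies with genetic-drift noise.

For class frequencies ``x_k`` the drift combines selection against the mean
mutation load and the mutation flux from class k-1,

    dx_k = [ -s (k - kbar) x_k + U (x_{k-1} - x_k) ] dt + sqrt(x_k / N_e) dW_k,

with ``kbar = sum_k k x_k`` and independent Wiener increments per class.  The
deterministic part has the Poisson(lam) profile as its unique attracting
fixed point.  The per-class noise amplitudes follow the standard
uncorrelated-white-noise form; projecting back onto the simplex after each
step (clamp at zero, renormalise) restores the multinomial covariance
structure to leading order.  Time is measured in Moran generations, whose
drift variance is twice the Wright-Fisher one, so the effective size is
``N_e = N / 2`` for a Moran population of N — this makes diffusion(N),
Moran(N) and Wright-Fisher(N/2) directly comparable.

Integration is Euler-Maruyama (Ito); any strong-order >= 0.5 scheme is
admissible here since the acceptance surface is step-size self-convergence
plus agreement with both microscopic models, and those are tested.

A click is declared when the fittest-class frequency falls below the
absorption threshold ``x_abs = 1/(2N)`` — half an individual, the natural
microscopic resolution below which the noise term is ill-defined.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .moran import class_window
from .params import FullParams, haigh_steady_state
from .results import ClickTimeSample
from dataclasses import dataclass


@dataclass
class FrequencyState:
    """Real-valued class frequencies over the window; sums to one."""

    x: np.ndarray
    t: float = 0.0
    k_min: int = 0


def default_dt(params: FullParams, K: int | None = None) -> float:
    """Conservative step: 0.01 over the fastest deterministic rate."""
    if K is None:
        K = class_window(params)
    return 0.01 / max(params.s * K, params.U, 1.0)


def drift(x: np.ndarray, params: FullParams) -> np.ndarray:
    """Deterministic part: selection against the mean load plus mutation
    flux; the outflow of the last window class is suppressed (mass folding)."""
    K = len(x)
    k = np.arange(K)
    # mean load relative to the current total: keeps the drift exactly
    # mass-conserving even slightly off the simplex
    kbar = float(k @ x) / float(x.sum())
    d = -params.s * (k - kbar) * x
    d[1:] += params.U * x[:-1]
    d[:-1] -= params.U * x[:-1]
    return d


def initial_frequencies(params: FullParams, K: int | None = None) -> FrequencyState:
    """Haigh equilibrium profile on the window (tail folded)."""
    if K is None:
        K = class_window(params)
    pi, tail = haigh_steady_state(params.lam, K - 1)
    x = pi.copy()
    x[-1] += tail
    return FrequencyState(x=x)


def sde_step(
    state: FrequencyState,
    params: FullParams,
    dt: float,
    rng: np.random.Generator,
) -> FrequencyState:
    """One Euler-Maruyama step (reference implementation): drift, per-class
    genetic-drift noise, clamp at zero, renormalise onto the simplex.

    The step is adaptively halved (up to 20 times) if any pre-clamp
    frequency undershoots below -10 sqrt(dt/N): that signals a step too
    coarse for the current noise amplitude.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    Ne = params.N / 2.0
    for _ in range(20):
        noise = rng.standard_normal(len(state.x))
        x_new = (
            state.x
            + drift(state.x, params) * dt
            + np.sqrt(np.maximum(state.x, 0.0) / Ne * dt) * noise
        )
        if x_new.min() >= -10.0 * np.sqrt(dt / params.N):
            break
        dt /= 2.0
    else:
        raise RuntimeError("sde_step: persistent undershoot, dt will not refine")
    np.clip(x_new, 0.0, None, out=x_new)
    x_new /= x_new.sum()
    return FrequencyState(x=x_new, t=state.t + dt, k_min=state.k_min)


@njit(cache=True)
def _sde_first_click_kernel(x0, N, U, s, dt, x_abs, reps, max_steps, seed):
    """First click time (generations) per replicate; -1 marks censoring."""
    np.random.seed(seed)
    K = x0.shape[0]
    Ne = N / 2.0
    sq = np.sqrt(dt / Ne)
    out = np.empty(reps)
    x = np.empty(K)
    xn = np.empty(K)
    for r in range(reps):
        for j in range(K):
            x[j] = x0[j]
        t = -1.0
        for step in range(1, max_steps + 1):
            kbar = 0.0
            for j in range(K):
                kbar += j * x[j]
            tot = 0.0
            for j in range(K):
                d = -s * (j - kbar) * x[j]
                if j > 0:
                    d += U * x[j - 1]
                if j < K - 1:
                    d -= U * x[j]
                v = x[j] + d * dt + np.sqrt(x[j]) * sq * np.random.normal()
                if v < 0.0:
                    v = 0.0
                xn[j] = v
                tot += v
            for j in range(K):
                x[j] = xn[j] / tot
            if x[0] <= x_abs:
                t = step * dt
                break
        out[r] = t
    return out


def sde_click_times(
    params: FullParams,
    reps: int,
    dt: float | None = None,
    seed: int = 0,
    max_generations: float = 1e5,
    x_abs: float | None = None,
) -> ClickTimeSample:
    """Time to first click per replicate by Euler-Maruyama integration.

    ``x_abs`` defaults to 1/(2N); the manifest metadata records dt, the
    scheme and the threshold for provenance.
    """
    if dt is None:
        dt = default_dt(params)
    if x_abs is None:
        x_abs = 1.0 / (2.0 * params.N)
    state = initial_frequencies(params)
    max_steps = int(max_generations / dt)
    times = _sde_first_click_kernel(
        state.x,
        params.N,
        params.U,
        params.s,
        dt,
        x_abs,
        reps,
        max_steps,
        seed,
    )
    ok = times > 0
    return ClickTimeSample(
        times=times[ok],
        model="diffusion",
        seed=seed,
        params=params,
        censored=int((~ok).sum()),
        censored_time=max_generations,
        meta={"dt": dt, "scheme": "euler-maruyama", "x_abs": x_abs},
    )
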