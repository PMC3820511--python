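"""The reduced two-class Moran model of Muller's ratchet.

The fittest class holds ``n`` of the ``N`` individuals; the remaining
``N - n`` form a single mutated background with relative fitness
``1 - s_eff``.  At each elementary step one individual reproduces (chosen
proportionally to class fitness), its offspring leaves the fittest class with
probability ``u``, and one individual dies uniformly at random.  The count
``n`` therefore performs a lazy birth-death chain on {0..N} with per-step
probabilities

    t_plus(n)  = [n / (n + (1-s)(N-n))] * (1-u) * (N-n)/N
    t_minus(n) = [((1-s)(N-n) + u n) / (n + (1-s)(N-n))] * n/N

(``s`` short for ``s_eff``); ``n = 0`` is absorbing (a ratchet click) and the
chain reflects at ``N``.  Everything in this module is exact for this chain:
the mean click time via the classical first-passage product formula, its
independent linear-system check, the quasi-stationary distribution and decay
rate via the dominant eigenpair of the sub-stochastic transition operator,
direct time integration of the master equation, and Monte Carlo simulation.

Time is reported in generations throughout (1 generation = N steps).
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.linalg import eigh_tridiagonal, solve_banded

from .params import TwoClassParams
from .results import ClickTimeSample, QSDTable

from dataclasses import dataclass


@dataclass(frozen=True)
class TransitionRates:
    """Per-step birth-death probabilities of the fittest-class count.

    ``t_plus[n]`` / ``t_minus[n]`` are the probabilities of ``n -> n+1`` /
    ``n -> n-1`` in one elementary Moran step; the residual
    ``1 - t_plus - t_minus`` is the probability of staying put (lazy chain).
    """

    t_plus: np.ndarray
    t_minus: np.ndarray
    params: TwoClassParams

    @property
    def N(self) -> int:
        return self.params.N


def build_rates(params: TwoClassParams) -> TransitionRates:
    """Assemble the birth-death transition probabilities for ``n = 0..N``.

    Boundary conditions: ``t_plus[0] = t_minus[0] = 0`` (absorbing click
    state) and ``t_plus[N] = 0`` (nobody left to mutate into the background
    by displacement; reflecting top).
    """
    N, u, s = params.N, params.u, params.s_eff
    n = np.arange(N + 1, dtype=np.float64)
    denom = n + (1.0 - s) * (N - n)  # fitness-weighted reproduction pool
    with np.errstate(invalid="ignore", divide="ignore"):
        t_plus = (n / denom) * (1.0 - u) * (N - n) / N
        t_minus = (((1.0 - s) * (N - n) + u * n) / denom) * (n / N)
    t_plus[0] = 0.0
    t_minus[0] = 0.0
    t_plus[N] = 0.0
    return TransitionRates(t_plus=t_plus, t_minus=t_minus, params=params)


def default_n0(params: TwoClassParams) -> int:
    """Initial condition used throughout: the deterministic equilibrium
    occupancy ``round(N * x_star)``, clipped into {1..N}."""
    return int(min(max(round(params.N * params.x_star), 1), params.N))


# ----------------------------------------------------------------------
# exact mean first-passage time
# ----------------------------------------------------------------------

def exact_mfpt(rates: TransitionRates, n0: int | None = None) -> float:
    """Exact mean click time (generations) from ``n0`` fittest individuals.

    Evaluates the classical product formula for the mean first-passage time
    of a birth-death chain to the absorbing state 0,

        tau(n0) = sum_{k=1}^{n0} sum_{j=k}^{N} (1/t_minus[j])
                  prod_{i=k}^{j-1} t_plus[i]/t_minus[i]

    in Moran steps, then divides by N.  All products and sums are
    accumulated in the log domain (running log-sum-exp), so the result does
    not overflow even when the MFPT exceeds the double-precision range of
    intermediate products.

    Returns ``inf`` if absorption is unreachable from above (some
    ``t_minus[n] == 0`` with ``t_plus[n] > 0`` below ``n0``).
    """
    N = rates.N
    if n0 is None:
        n0 = default_n0(rates.params)
    if not (1 <= n0 <= N):
        raise ValueError(f"n0 must lie in 1..{N}, got {n0}")
    tp = rates.t_plus
    tm = rates.t_minus
    # a state with no down-move anywhere at or below n0 blocks absorption
    if np.any(tm[1 : n0 + 1] == 0.0):
        return float("inf")
    # L[m-1] = ln prod_{i=1}^{m-1} tp[i]/tm[i],  m = 1..N
    with np.errstate(divide="ignore"):
        log_ratio = np.log(tp[1:N]) - np.log(tm[1:N])
        a = np.concatenate([[0.0], np.cumsum(log_ratio)]) - np.log(tm[1 : N + 1])
    # suffix log-sum-exp  G[k-1] = ln sum_{j>=k} exp(a_j)
    G = np.empty(N)
    G[-1] = a[-1]
    for k in range(N - 2, -1, -1):
        G[k] = np.logaddexp(a[k], G[k + 1])
    L = np.concatenate([[0.0], np.cumsum(log_ratio)])
    terms = G[:n0] - L[:n0]
    m = terms.max()
    log_tau_steps = m + np.log(np.exp(terms - m).sum())
    return float(np.exp(log_tau_steps - np.log(N)))


def mfpt_linear_solve(rates: TransitionRates, method: str = "rational") -> np.ndarray:
    """Independent first-passage oracle: solve the first-step equations.

    ``T(n) = 1 + t_plus T(n+1) + t_minus T(n-1) + (1 - t_plus - t_minus) T(n)``
    with ``T(0) = 0`` and reflection at N, as a tridiagonal linear system.
    Returns T(1..N) in generations.

    ``method="rational"`` (default) runs the Thomas elimination in exact
    rational arithmetic on the binary transition probabilities, so the
    returned times are correctly rounded even in deep-barrier regimes where
    the system's condition number (of order of the MFPT itself, easily
    1e10+) defeats double precision; ``method="float"`` uses the LAPACK
    banded solver and is adequate away from those corners.
    """
    N = rates.N
    lam = rates.t_plus[1 : N + 1]
    mu = rates.t_minus[1 : N + 1]
    if method == "float":
        ab = np.zeros((3, N))
        ab[1, :] = lam + mu
        ab[0, 1:] = -lam[:-1]
        ab[2, :-1] = -mu[1:]
        T = solve_banded((1, 1), ab, np.ones(N))
        return T / N
    if method != "rational":
        raise ValueError(f"unknown method {method!r}")
    from fractions import Fraction

    a = [Fraction(x) for x in mu]    # subdiagonal (coefficient of T_{n-1})
    b = [Fraction(x) + Fraction(y) for x, y in zip(lam, mu)]  # diagonal
    c = [Fraction(x) for x in lam]   # superdiagonal
    one = Fraction(1)
    # forward elimination (no pivoting: diagonally dominant M-matrix)
    cp = [Fraction(0)] * N
    dp = [Fraction(0)] * N
    cp[0] = c[0] / b[0]
    dp[0] = one / b[0]
    for i in range(1, N):
        denom = b[i] - a[i] * cp[i - 1]
        cp[i] = c[i] / denom if i < N - 1 else Fraction(0)
        dp[i] = (one + a[i] * dp[i - 1]) / denom
    T = [Fraction(0)] * N
    T[-1] = dp[-1]
    for i in range(N - 2, -1, -1):
        T[i] = dp[i] + cp[i] * T[i + 1]
    return np.array([float(t) for t in T]) / N


# ----------------------------------------------------------------------
# quasi-stationary distribution and decay rate (eigen oracle)
# ----------------------------------------------------------------------

def qsd_eigen(rates: TransitionRates, dense_cap: int = 5000) -> tuple[float, QSDTable]:
    """Dominant eigenpair of the transition operator restricted to {1..N}.

    The per-step operator ``M`` (sub-stochastic: probability leaks to the
    absorbing state through ``t_minus[1]``) is symmetrised by the standard
    birth-death similarity transform, and the largest eigenpair is obtained
    with a symmetric tridiagonal eigensolver.  The left Perron eigenvector,
    recovered in the log domain to avoid overflow of the similarity weights,
    is the quasi-stationary distribution; the click rate per generation is
    ``(1 - eigenvalue) * N`` and satisfies the flux identity
    ``rate = N * t_minus[1] * qsd[1]``.
    """
    N = rates.N
    if N > dense_cap:
        raise ValueError(f"N={N} exceeds the dense eigensolver cap {dense_cap}")
    lam = rates.t_plus[1 : N + 1]
    mu = rates.t_minus[1 : N + 1]
    diag = 1.0 - lam - mu
    off = np.sqrt(lam[:-1] * mu[1:])
    w, v = eigh_tridiagonal(diag, off, select="i", select_range=(N - 1, N - 1))
    eigenvalue = float(w[0])
    vec = v[:, 0]
    # left eigenvector of M: q_n = vec_n * d_n with
    # d_n = prod_{i<n} sqrt(lam_i / mu_{i+1})   (log domain)
    log_d = np.concatenate([[0.0], 0.5 * np.cumsum(np.log(lam[:-1]) - np.log(mu[1:]))])
    with np.errstate(divide="ignore"):
        log_q = np.log(np.abs(vec)) + log_d
    sign = np.sign(vec)
    if sign[np.argmax(log_q)] < 0:
        sign = -sign
    q = sign * np.exp(log_q - log_q.max())
    q[q < 0] = 0.0  # Perron vector is positive; clip eigensolver noise
    q /= q.sum()
    rate = (1.0 - eigenvalue) * N
    flags = {
        "eigenvalue": eigenvalue,
        "flux_rate": float(N * rates.t_minus[1] * q[0]),
        "spectral_gap_ok": True,
    }
    table = QSDTable(support=np.arange(1, N + 1), mass=q, source="eigen", flags=flags)
    return rate, table


# ----------------------------------------------------------------------
# master-equation time integration
# ----------------------------------------------------------------------

def evolve_master(
    rates: TransitionRates,
    p0: np.ndarray,
    n_steps: int,
    record_every: int = 0,
) -> dict:
    """Explicitly step the master equation for P(n, t), n = 0..N.

    ``p0`` is the initial distribution over 0..N (state 0 absorbing).  One
    call advances ``n_steps`` elementary Moran steps.  Returns the final
    distribution, the total probability (absorbed mass included, for
    conservation checks) and, if ``record_every > 0``, the survival
    probability sampled every that many steps.
    """
    N = rates.N
    p = np.asarray(p0, dtype=np.float64).copy()
    if p.shape != (N + 1,):
        raise ValueError(f"p0 must have shape ({N + 1},)")
    tp = rates.t_plus
    tm = rates.t_minus
    stay = 1.0 - tp - tm
    survival = []
    for step in range(1, n_steps + 1):
        new = p * stay
        new[1:] += p[:-1] * tp[:-1]
        new[:-1] += p[1:] * tm[1:]
        p = new
        if record_every and step % record_every == 0:
            survival.append(1.0 - p[0])
    return {
        "p": p,
        "total": float(p.sum()),
        "survival": np.array(survival),
        "record_every": record_every,
        "steps": n_steps,
    }


# ----------------------------------------------------------------------
# Monte Carlo simulation
# ----------------------------------------------------------------------

@njit(cache=True)
def _mc_kernel(tp, tm, n0, reps, seed, max_steps, jump_chain):
    """Absorption times (steps) of the birth-death chain, one per replicate.

    jump_chain=True samples geometric holding times between moves, which is
    equivalent in distribution to per-step simulation of the lazy chain.
    """
    np.random.seed(seed)
    times = np.empty(reps)
    censored = 0
    for r in range(reps):
        n = n0
        steps = 0.0
        t = -1.0
        while steps < max_steps:
            p_move = tp[n] + tm[n]
            if p_move <= 0.0:
                break  # frozen interior state: cannot absorb
            if jump_chain:
                steps += np.random.geometric(p_move)
            else:
                steps += 1.0
                if np.random.random() >= p_move:
                    continue
            if np.random.random() * p_move < tp[n]:
                n += 1
            else:
                n -= 1
            if n == 0:
                t = steps
                break
        if t < 0.0:
            censored += 1
            times[r] = -max_steps
        else:
            times[r] = t
    return times, censored


def mc_click_times(
    params: TwoClassParams,
    n0: int | None = None,
    reps: int = 1000,
    seed: int = 0,
    max_steps: float = 1e12,
    jump_chain: bool = True,
) -> ClickTimeSample:
    """Monte Carlo click times of the two-class chain, in generations.

    Uses the jump-chain construction (geometric holding times) by default;
    ``jump_chain=False`` simulates every elementary step, which is slower but
    distributionally identical — the agreement of the two is tested.
    Replicates that exceed ``max_steps`` are censored, not discarded
    silently.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rates = build_rates(params)
    if n0 is None:
        n0 = default_n0(params)
    times, censored = _mc_kernel(
        rates.t_plus, rates.t_minus, n0, reps, seed, float(max_steps), jump_chain
    )
    ok = times > 0
    return ClickTimeSample(
        times=times[ok] / params.N,
        model="twoclass_mc",
        seed=seed,
        params=params,
        censored=censored,
        censored_time=float(max_steps) / params.N,
        meta={"n0": n0, "jump_chain": jump_chain},
    )
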