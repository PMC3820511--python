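"""Parameter containers, the Haigh mutation-selection equilibrium, and the
mapping from the full multi-class ratchet to the effective two-class model.

The full ratchet is parametrised by the population size ``N``, the genomic
deleterious mutation rate ``U`` (per genome per generation) and the selection
coefficient ``s`` per mutation; an individual carrying ``k`` mutations has
fitness ``(1 - s)**k``.  In an infinite population, mutation pressure and
selection balance at a Poisson profile with mean ``lam = U / s`` over the
mutation classes, so the fittest (mutation-free) class holds a fraction
``exp(-lam)`` of the population.

The two-class reduction keeps the fittest class explicit and merges every
mutated class into a single background with effective selection disadvantage
``s_eff`` and with mutation rate ``u`` out of the fittest class.  The
effective parameters are fixed by requiring that, at the infinite-population
equilibrium, (i) the mean fitness of the whole population and (ii) the mean
fitness of the mutated individuals agree between the two models, and that the
mutation rate out of the fittest class is the same in both.  With Poisson
distributed mutation numbers the out-rate of the fittest class is
``u = 1 - exp(-U)``, and the two fitness conditions then give

    s_eff = (1 - exp(-U)) / (1 - exp(-lam)),
    lam0  = u / s_eff = 1 - exp(-lam),

so the equilibrium frequency of the fittest class, ``x_star = 1 - lam0``,
equals ``exp(-lam)`` — the Haigh value — by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


class RegimeWarning(UserWarning):
    """A result was requested outside the regime its approximation assumes."""


@dataclass(frozen=True)
class FullParams:
    """Parameters of the full multi-class ratchet.

    Attributes
    ----------
    N : int
        Population size (constant).
    U : float
        Deleterious mutation rate per genome per generation, ``U >= 0``.
    s : float
        Selection coefficient per mutation, ``0 < s < 1``.
    """

    N: int
    U: float
    s: float

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"population size must be >= 1, got N={self.N}")
        if not (0.0 <= self.s < 1.0):
            # s = 0 is admitted for the neutral limit used in validation
            raise ValueError(f"selection coefficient must lie in [0, 1), got s={self.s}")
        if self.U < 0.0:
            raise ValueError(f"mutation rate must be >= 0, got U={self.U}")

    @property
    def lam(self) -> float:
        """Rescaled mutation rate ``U / s`` (recomputed, never stored)."""
        if self.U == 0.0:
            return 0.0
        if self.s == 0.0:
            return math.inf
        return self.U / self.s


@dataclass(frozen=True)
class TwoClassParams:
    """Effective parameters of the reduced fittest-class/background model.

    ``u`` is the per-reproduction probability that an offspring of a fittest
    individual leaves the fittest class; ``s_eff`` the selection disadvantage
    of the merged mutated class.  The deterministic dynamics have an interior
    fixed point only for ``u < s_eff``.
    """

    N: int
    u: float
    s_eff: float

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"population size must be >= 1, got N={self.N}")
        if not (0.0 < self.s_eff < 1.0):
            raise ValueError(f"s_eff must lie in (0, 1), got {self.s_eff}")
        if not (0.0 <= self.u < 1.0):
            raise ValueError(f"u must lie in [0, 1), got {self.u}")

    @property
    def lam0(self) -> float:
        """Rescaled mutation rate ``u / s_eff`` of the reduced model."""
        return self.u / self.s_eff

    @property
    def x_star(self) -> float:
        """Deterministic equilibrium frequency ``1 - u/s_eff`` of the fittest
        class (0 if the mutation pressure exceeds the selection penalty)."""
        return max(1.0 - self.lam0, 0.0)


def haigh_steady_state(lam: float, k_max: int | None = None) -> tuple[np.ndarray, float]:
    """Infinite-population mutation-selection equilibrium over classes 0..k_max.

    Returns the Poisson(``lam``) probabilities ``pi_k = exp(-lam) lam^k / k!``
    for ``k <= k_max`` together with the tail mass beyond ``k_max``.

    Parameters
    ----------
    lam : float
        Rescaled mutation rate ``U / s``; must be >= 0.
    k_max : int, optional
        Highest class retained.  Defaults to ``round(10 * (lam + 1)) + 20``,
        where the Poisson tail is negligible for any regime of interest.
    """
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam}")
    if k_max is None:
        k_max = int(round(10 * (lam + 1))) + 20
    if k_max < 0:
        raise ValueError(f"k_max must be >= 0, got {k_max}")
    k = np.arange(k_max + 1)
    pi = stats.poisson.pmf(k, lam)
    tail = float(stats.poisson.sf(k_max, lam))
    return pi, tail


def map_parameters(full: FullParams, u_convention: str = "poisson_total") -> TwoClassParams:
    """Map full-ratchet parameters ``(N, U, s)`` to the two-class model.

    The mutation rate out of the fittest class is matched between the models:
    with Poisson(U) mutation numbers per reproduction this is
    ``u = 1 - exp(-U)`` (``u_convention="poisson_total"``); the alternative
    ``"linear"`` convention sets ``u = U`` for sensitivity analysis.  The
    effective selection coefficient then follows from equating the mean
    fitness of the mutated individuals, ``s_eff = u / (1 - exp(-lam))``, which
    also reproduces the full model's mean population fitness and places the
    two-class equilibrium at ``x_star = exp(-lam)``.

    Emits a :class:`RegimeWarning` (but still returns) when the expected
    fittest-class occupancy ``N * exp(-lam)`` falls below one individual,
    where the reduction loses its meaning.
    """
    if u_convention not in ("poisson_total", "linear"):
        raise ValueError(f"unknown u_convention {u_convention!r}")
    N, s = full.N, full.s
    lam = full.lam
    if full.U == 0.0:
        # no mutation: classes decouple and the reduction is trivial
        return TwoClassParams(N=N, u=0.0, s_eff=s)
    u = -math.expm1(-full.U) if u_convention == "poisson_total" else full.U
    s_eff = u / -math.expm1(-lam)
    if N * math.exp(-lam) < 1.0:
        warnings.warn(
            f"N*exp(-lam) = {N * math.exp(-lam):.3g} < 1: two-class reduction "
            "outside its validity regime (fittest class not maintained)",
            RegimeWarning,
            stacklevel=2,
        )
    return TwoClassParams(N=N, u=u, s_eff=s_eff)


def equilibrium_fittest_count(params: FullParams) -> float:
    """Expected fittest-class occupancy ``N * exp(-lam)`` at the Haigh
    equilibrium."""
    return params.N * math.exp(-params.lam)
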