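"""Shared result containers for click-time samples and fittest-class
distributions."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass
class ClickTimeSample:
    """First-passage (click) times collected from one model.

    Attributes
    ----------
    times : ndarray
        Observed click times in generations (one Moran generation = N
        elementary birth-death steps; one Wright-Fisher generation = one
        resampling sweep).  All entries are > 0.
    model : str
        Producing model, one of ``moran``, ``wright_fisher``, ``diffusion``,
        ``twoclass_mc``.
    seed : int
        RNG seed used to generate the sample.
    params : object
        The FullParams or TwoClassParams the sample was generated under.
    censored : int
        Number of replicates that exhausted the step budget before clicking.
    censored_time : float
        Time (generations) at which censored replicates were abandoned.
    """

    times: np.ndarray
    model: str
    seed: int
    params: Any
    censored: int = 0
    censored_time: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.times)

    @property
    def mean(self) -> float:
        return float(np.mean(self.times)) if self.n else float("nan")

    @property
    def se(self) -> float:
        """Standard error of the mean click time."""
        if self.n < 2:
            return float("nan")
        return float(np.std(self.times, ddof=1) / np.sqrt(self.n))


@dataclass
class QSDTable:
    """Probability mass over the fittest-class occupancy n = 1..N.

    ``source`` records the provenance: ``wkb_leading``, ``wkb_prefactor``,
    ``eigen`` (numerical eigenvector oracle) or ``simulation`` (histogram).
    ``flags`` carries machine-checkable validity diagnostics.
    """

    support: np.ndarray
    mass: np.ndarray
    source: str
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.support.shape != self.mass.shape:
            raise ValueError("support and mass must have equal shapes")

    @property
    def frequencies(self) -> np.ndarray:
        """Support rescaled to frequencies x = n / N."""
        return self.support / self.support[-1] if len(self.support) else self.support

    def mode(self) -> int:
        return int(self.support[np.argmax(self.mass)])


def total_variation(p: QSDTable | np.ndarray, q: QSDTable | np.ndarray) -> float:
    """Total-variation distance between two distributions on 1..N.

    Accepts QSDTable objects (aligned on their integer support) or raw mass
    vectors of equal length.
    """
    if isinstance(p, QSDTable) and isinstance(q, QSDTable):
        lo = int(min(p.support[0], q.support[0]))
        hi = int(max(p.support[-1], q.support[-1]))
        pv = np.zeros(hi - lo + 1)
        qv = np.zeros(hi - lo + 1)
        pv[p.support.astype(int) - lo] = p.mass
        qv[q.support.astype(int) - lo] = q.mass
    else:
        pv = np.asarray(p, dtype=float)
        qv = np.asarray(q, dtype=float)
        if pv.shape != qv.shape:
            raise ValueError("mass vectors must have equal length")
    return 0.5 * float(np.abs(pv - qv).sum())
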