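"""Desk-scale comparison studies: click-time agreement across models and
quasi-stationary-distribution agreement between simulation, eigen oracle and
WKB analytics.

These orchestrators are the integration surface of the package: they run the
same parameter points through the requested models (full Moran, Wright-Fisher
at half population size, diffusion, two-class Monte Carlo, exact two-class
MFPT, WKB) and emit a long-format table with means, standard errors,
censoring counts and validity flags.  A budget estimator predicts the total
elementary-step cost from the mapped two-class exact MFPT before any
simulation starts and refuses grids that would not finish at desk scale
(override with ``force=True``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import diffusion, moran, twoclass, wkb, wright_fisher
from .params import FullParams, map_parameters
from .results import QSDTable, total_variation

KNOWN_MODELS = (
    "moran",
    "wright_fisher",
    "diffusion",
    "twoclass_mc",
    "exact",
    "wkb_full",
    "wkb_simplified",
)


@dataclass
class ComparisonGrid:
    """Parameter points plus the models and replicate count to run them on."""

    points: list[FullParams]
    replicates: int = 1000
    seed: int = 0
    models: tuple[str, ...] = ("moran", "exact")
    sde_dt: float | None = None

    def __post_init__(self) -> None:
        for m in self.models:
            if m not in KNOWN_MODELS:
                raise ValueError(f"unknown model {m!r}; choose from {KNOWN_MODELS}")

    def grouping(self) -> pd.DataFrame:
        """Grouping keys used throughout: the rescaled mutation rate lam and
        the rescaled selection strength N*s (equivalently N*U)."""
        return pd.DataFrame(
            {
                "N": [p.N for p in self.points],
                "U": [p.U for p in self.points],
                "s": [p.s for p in self.points],
                "lam": [p.lam for p in self.points],
                "Ns": [p.N * p.s for p in self.points],
            }
        )


def estimate_cost(grid: ComparisonGrid) -> float:
    """Predicted total elementary-step count over all simulation models."""
    total = 0.0
    for p in grid.points:
        mte = twoclass.exact_mfpt(twoclass.build_rates(map_parameters(p)))
        if not np.isfinite(mte):
            mte = 1e5
        per_click_steps = mte * p.N
        for m in grid.models:
            if m in ("moran", "twoclass_mc"):
                total += per_click_steps * grid.replicates
            elif m == "wright_fisher":
                total += mte * grid.replicates * 50  # one gen ~ 50 step-units
            elif m == "diffusion":
                dt = grid.sde_dt or diffusion.default_dt(p)
                total += mte / dt * grid.replicates * moran.class_window(p)
    return total


def run_comparison(
    grid: ComparisonGrid,
    force: bool = False,
    budget: float = 5e9,
) -> pd.DataFrame:
    """Mean click times per (model, parameter point), long format.

    Deterministic given the grid seed: model m at point i uses seed
    ``grid.seed + 1000 * i + offset(m)``.
    """
    cost = estimate_cost(grid)
    if cost > budget and not force:
        raise RuntimeError(
            f"estimated cost {cost:.3g} step-units exceeds budget {budget:.3g}; "
            "reduce replicates/points or pass force=True"
        )
    rows = []
    for i, p in enumerate(grid.points):
        tc = map_parameters(p)
        flags = wkb._validity_flags(tc) if tc.u < tc.s_eff else {"in_regime": False}
        for m in grid.models:
            seed = grid.seed + 1000 * i + KNOWN_MODELS.index(m)
            mean = se = np.nan
            n_reps = censored = 0
            if m == "moran":
                s = moran.first_click_times(p, grid.replicates, seed=seed)
                mean, se, n_reps, censored = s.mean, s.se, s.n, s.censored
            elif m == "wright_fisher":
                s = wright_fisher.wf_click_times(
                    wright_fisher.halved_population(p), grid.replicates, seed=seed
                )
                mean, se, n_reps, censored = s.mean, s.se, s.n, s.censored
            elif m == "diffusion":
                s = diffusion.sde_click_times(
                    p, grid.replicates, dt=grid.sde_dt, seed=seed
                )
                mean, se, n_reps, censored = s.mean, s.se, s.n, s.censored
            elif m == "twoclass_mc":
                s = twoclass.mc_click_times(tc, reps=grid.replicates, seed=seed)
                mean, se, n_reps, censored = s.mean, s.se, s.n, s.censored
            elif m == "exact":
                mean, se = twoclass.exact_mfpt(twoclass.build_rates(tc)), 0.0
            elif m == "wkb_full":
                mean, se = wkb.wkb_mte(tc).mte, 0.0
            elif m == "wkb_simplified":
                mean, se = wkb.wkb_mte_simplified(tc).mte, 0.0
            rows.append(
                {
                    "model": m,
                    "N": p.N,
                    "U": p.U,
                    "s": p.s,
                    "lam": p.lam,
                    "lam0": tc.lam0,
                    "s_eff": tc.s_eff,
                    "mean_click_time": mean,
                    "SE": se,
                    "n_reps": n_reps,
                    "censored": censored,
                    "in_regime": bool(flags.get("in_regime", False)),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class QSDStudy:
    """Bundle of fittest-class distributions and their pairwise distances."""

    histogram: QSDTable
    eigen: QSDTable
    wkb_prefactor: QSDTable
    wkb_leading: QSDTable
    eigen_rate: float
    tv: dict = field(default_factory=dict)


def run_qsd_study(
    params: FullParams,
    replicates: int = 5000,
    seed: int = 0,
    sample_fraction: float = 0.1,
) -> QSDStudy:
    """Full-ratchet histogram vs two-class eigen oracle vs WKB QSDs.

    Composes the Moran occupancy histogram at a fraction of the click time,
    the dominant-eigenvector QSD of the mapped two-class chain, and both WKB
    orders; reports pairwise total-variation distances.  Out-of-regime
    parameters produce flags and larger distances, never a crash.
    """
    tc = map_parameters(params)
    rate, eigen = twoclass.qsd_eigen(twoclass.build_rates(tc))
    hist = moran.sample_fittest_histogram(
        params, replicates=replicates, sample_fraction=sample_fraction, seed=seed
    )
    pref = wkb.wkb_qsd(tc, order="prefactor")
    lead = wkb.wkb_qsd(tc, order="leading")
    tv = {
        "simulation_vs_eigen": total_variation(hist, eigen),
        "wkb_prefactor_vs_eigen": total_variation(pref, eigen),
        "wkb_leading_vs_eigen": total_variation(lead, eigen),
    }
    return QSDStudy(
        histogram=hist,
        eigen=eigen,
        wkb_prefactor=pref,
        wkb_leading=lead,
        eigen_rate=rate,
        tv=tv,
    )
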