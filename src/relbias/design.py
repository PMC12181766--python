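"""Optimal study design under a reliability/sample-size budget.

Better instruments (higher reliability) and more subjects both cost money;
residual confounding punishes a cheap confounder instrument with inflated
type-I error.  This module makes that trade-off concrete: an exhaustive
grid search over exposure reliability r_x, confounder reliability r_z and
sample size n, minimizing analytic false power subject to

    cost = kappa_n * n + kappa_x * c(r_x) + kappa_z * c(r_z) <= budget,

with the default reliability-cost function c(r) = r / (1 - r) — convex and
diverging as r -> 1, so perfect measurement is unattainable at finite cost.
The cost function is pluggable; no canonical form exists for instrument
cost, this one simply encodes "each extra point of reliability costs more
than the last".

Because the structural models contain no direct exposure -> outcome path,
false power is the entire objective; a recurring outcome of the search is
that spending on the *confounder* instrument (the nuisance variable) beats
spending on the exposure instrument — measured reliably, the confounder can
actually be adjusted away.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, InfeasibleDesignError
from . import analytic
from .inference import TestSpec, false_power

__all__ = ["CostModel", "DesignResult", "AllocationReport", "optimize_design", "allocation_report"]


def odds_cost(r: np.ndarray) -> np.ndarray:
    """Default cost of reliability r: the odds transform r / (1 - r)."""
    r = np.asarray(r, dtype=float)
    return r / (1.0 - r)


@dataclass(frozen=True)
class CostModel:
    """Linear budget over subjects and the two instruments.

    kappa_x / kappa_z scale the cost of reliability (through
    ``reliability_cost``) for the exposure / confounder instrument;
    kappa_n is the marginal cost per subject.
    """

    kappa_x: float
    kappa_z: float
    kappa_n: float
    budget: float
    reliability_cost: Callable[[np.ndarray], np.ndarray] = field(default=odds_cost)

    def __post_init__(self) -> None:
        for name in ("kappa_x", "kappa_z", "kappa_n"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be nonnegative")
        if self.budget <= 0:
            raise DomainError("budget must be positive")

    def cost(self, r_x: np.ndarray, r_z: np.ndarray, n: np.ndarray) -> np.ndarray:
        return (
            self.kappa_n * np.asarray(n, dtype=float)
            + self.kappa_x * self.reliability_cost(r_x)
            + self.kappa_z * self.reliability_cost(r_z)
        )


@dataclass(frozen=True)
class DesignResult:
    """Winning design and the cost/false-power frontier of the search."""

    best: tuple[float, float, int]  # (alpha_x, alpha_z, n)
    achieved_false_power: float
    achieved_cost: float
    frontier: list[tuple[float, float]]  # (cost, false_power), cost ascending
    spend_x: float
    spend_z: float
    spend_n: float

    def to_dict(self) -> dict:
        return {
            "alpha_x": self.best[0],
            "alpha_z": self.best[1],
            "n": self.best[2],
            "achieved_false_power": self.achieved_false_power,
            "achieved_cost": self.achieved_cost,
            "spend_exposure_instrument": self.spend_x,
            "spend_confounder_instrument": self.spend_z,
            "spend_subjects": self.spend_n,
            "frontier": [list(p) for p in self.frontier],
        }


def _default_n_grid(cost: CostModel, size: int) -> np.ndarray:
    if cost.kappa_n > 0:
        n_max = int(np.floor(cost.budget / cost.kappa_n))
    else:
        n_max = 10_000
    n_max = max(n_max, 5)
    grid = np.unique(np.round(np.geomspace(5, n_max, size)).astype(int))
    return grid[grid >= 5]


def optimize_design(
    beta: float,
    gamma: float,
    cost: CostModel,
    level: float = 0.05,
    r_grid_size: int = 41,
    n_grid_size: int = 20,
    r_max: float = 0.99,
    r_x_min: float = 0.0,
    n_grid: Optional[Sequence[int]] = None,
) -> DesignResult:
    """Exhaustive search minimizing analytic false power within budget.

    Reliabilities run on a uniform grid over [0, r_max] (the loading is the
    positive square root); sample sizes on a geometric grid from 5 up to
    what the budget allows.  Ties in false power are broken by lower cost,
    then lower n — so with no confounding (beta = 0) the cheapest feasible
    design wins.  Raises InfeasibleDesignError when no grid point fits the
    budget.

    Because the objective is false power under a null with no direct
    exposure effect, the unconstrained optimum is degenerate: an exposure
    instrument with zero reliability never rejects falsely.  Set ``r_x_min``
    to demand a minimally informative exposure measurement and obtain the
    non-trivial reliability/cost trade-off.
    """
    if not (0.0 <= r_x_min <= r_max):
        raise DomainError("r_x_min must lie in [0, r_max]")
    r_vals = np.linspace(0.0, r_max, r_grid_size)
    n_vals = np.asarray(n_grid, dtype=int) if n_grid is not None else _default_n_grid(cost, n_grid_size)
    if n_vals.size == 0 or np.any(n_vals < 5):
        raise DomainError("sample-size grid must contain integers >= 5")

    rx_vals = r_vals[r_vals >= r_x_min - 1e-12]
    if rx_vals.size == 0:
        rx_vals = np.array([r_x_min])
    rx, rz, nn = np.meshgrid(rx_vals, r_vals, n_vals, indexing="ij")
    costs = cost.cost(rx, rz, nn)
    feasible = costs <= cost.budget
    if not np.any(feasible):
        raise InfeasibleDesignError(
            f"budget {cost.budget} admits no design on the grid "
            f"(cheapest grid point costs {costs.min():.6g})"
        )

    ax, az = np.sqrt(rx), np.sqrt(rz)
    pr2 = analytic.partial_r2_model2(ax, az, beta, gamma)
    fp = np.empty_like(costs)
    for k, n in enumerate(n_vals):
        fp[:, :, k] = false_power(pr2[:, :, k], TestSpec(n=int(n), level=level))

    fp_f = np.where(feasible, fp, np.inf)
    # lexicographic argmin: false power, then cost, then n; residual ties
    # (e.g. a free instrument) resolved toward higher reliability, which is
    # never worse and insures against model misspecification
    order = np.lexsort(
        (-rx.ravel(), -rz.ravel(), nn.ravel(), costs.ravel(), fp_f.ravel())
    )
    idx = np.unravel_index(order[0], fp.shape)

    best = (float(ax[idx]), float(az[idx]), int(nn[idx]))
    spend_x = float(cost.kappa_x * cost.reliability_cost(rx[idx]))
    spend_z = float(cost.kappa_z * cost.reliability_cost(rz[idx]))
    spend_n = float(cost.kappa_n * nn[idx])

    # frontier: running minimum of false power over feasible designs by cost
    fc = costs[feasible].ravel()
    ff = fp[feasible].ravel()
    srt = np.argsort(fc, kind="stable")
    fc, ff = fc[srt], ff[srt]
    running = np.minimum.accumulate(ff)
    keep = np.concatenate(([True], running[1:] < running[:-1]))
    frontier = [(float(c), float(p)) for c, p in zip(fc[keep], running[keep])]

    return DesignResult(
        best=best,
        achieved_false_power=float(fp[idx]),
        achieved_cost=float(costs[idx]),
        frontier=frontier,
        spend_x=spend_x,
        spend_z=spend_z,
        spend_n=spend_n,
    )


@dataclass(frozen=True)
class AllocationReport:
    """Spend breakdown of a winning design."""

    table: pd.DataFrame
    confounder_exceeds_exposure: bool

    def __str__(self) -> str:
        lines = [self.table.to_string()]
        if self.confounder_exceeds_exposure:
            lines.append(
                "note: optimal spend on the confounder instrument exceeds spend "
                "on the exposure instrument — invest in measuring the nuisance "
                "variable well."
            )
        return "\n".join(lines)


def allocation_report(result: DesignResult) -> AllocationReport:
    """Tabulate spend on instruments vs subjects for a DesignResult.

    Flags the counterintuitive allocation in which improving the
    *confounder* instrument receives more budget than the exposure
    instrument.
    """
    total = result.spend_x + result.spend_z + result.spend_n
    spends = [result.spend_x, result.spend_z, result.spend_n]
    table = pd.DataFrame(
        {
            "component": [
                "exposure instrument (X')",
                "confounder instrument (Z')",
                "subjects (n)",
            ],
            "spend": spends,
            "fraction": [s / total if total > 0 else 0.0 for s in spends],
        }
    ).set_index("component")
    return AllocationReport(
        table=table,
        confounder_exceeds_exposure=bool(result.spend_z > result.spend_x),
    )
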