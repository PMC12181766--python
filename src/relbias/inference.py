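"""From population partial correlation to rejection probability.

Testing the exposure coefficient in the OLS regression of Y on (exposure,
Z') with intercept is a 1-degree-of-freedom partial F test (equivalently a
two-sided t test, F = t^2).  Under the structural models the exposure has no
direct effect on Y, so the population squared partial correlation rho_p^2
produced by measurement error is pure bias, and the probability of
rejecting at nominal level is "false power": type-I error inflation.

Analytically, the test statistic is distributed noncentral F(1, N-3, lambda)
with noncentrality lambda = (N-3) * f^2, where f^2 = rho_p^2 / (1 - rho_p^2)
is Cohen's effect size for a single added regressor.  False power is the
mass of that distribution above the central-F critical value; it equals the
nominal level exactly when rho_p^2 = 0 and grows with both rho_p^2 and N —
larger studies are *more* susceptible to spurious rejections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, SingularityError
from .path_models import ReliabilityLink
from . import analytic

__all__ = [
    "TestSpec",
    "paper_f_statistic",
    "hierarchical_f_statistic",
    "false_power",
    "bias_curve",
]

ArrayLike = Union[float, np.ndarray]

CURVE_FAMILIES = ("model1", "model2_constrained", "omega")


@dataclass(frozen=True)
class TestSpec:
    """Sample size and nominal level of the adjusted test.

    ``n`` must be at least 5 so the residual degrees of freedom, n - 3,
    are at least 2.
    """

    n: int
    level: float = 0.05

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 5:
            raise DomainError(f"n={self.n} must be an integer >= 5")
        object.__setattr__(self, "n", int(self.n))
        if not (0.0 < self.level < 1.0):
            raise DomainError(f"level={self.level} must lie in (0, 1)")

    @property
    def df_resid(self) -> int:
        return self.n - 3


def paper_f_statistic(r2_full: float, r2_reduced: float, n: int) -> float:
    """F expression built on the partial-correlation denominator.

    ``[(R2_full - R2_reduced) / (1 - R2_reduced)] * (n - 3)`` — i.e. the
    squared partial correlation times the residual degrees of freedom.  Note
    the denominator is 1 - R2_reduced, not the 1 - R2_full of the textbook
    hierarchical F (see :func:`hierarchical_f_statistic`); the bracket is
    then exactly the squared partial correlation, which is what makes the
    statistic a monotone function of the bias quantity studied here.
    """
    if r2_reduced >= 1.0 - analytic.SINGULARITY_TOL:
        raise SingularityError("1 - R2_reduced is numerically zero")
    if r2_full < r2_reduced - 1e-12:
        raise DomainError("r2_full must be >= r2_reduced")
    return (r2_full - r2_reduced) / (1.0 - r2_reduced) * (n - 3)


def hierarchical_f_statistic(r2_full: float, r2_reduced: float, n: int) -> float:
    """Standard 1-df hierarchical F: [(R2_full - R2_reduced)/(1 - R2_full)]*(n-3)."""
    if r2_full >= 1.0 - analytic.SINGULARITY_TOL:
        raise SingularityError("1 - R2_full is numerically zero")
    if r2_full < r2_reduced - 1e-12:
        raise DomainError("r2_full must be >= r2_reduced")
    return (r2_full - r2_reduced) / (1.0 - r2_full) * (n - 3)


def false_power(partial_r2: ArrayLike, spec: TestSpec) -> ArrayLike:
    """Rejection probability of the adjusted test at population partial R2.

    P(F' > F_crit) with F_crit the upper-``level`` quantile of the central
    F(1, n-3) and F' ~ noncentral F(1, n-3, lambda),
    lambda = (n-3) * partial_r2 / (1 - partial_r2).  Returns ``level``
    exactly at partial_r2 = 0.
    """
    pr2 = np.asarray(partial_r2, dtype=float)
    if np.any((pr2 < -1e-15) | (pr2 >= 1.0)):
        raise DomainError("partial_r2 must lie in [0, 1)")
    pr2 = np.clip(pr2, 0.0, None)
    dfd = spec.df_resid
    fcrit = stats.f.ppf(1.0 - spec.level, 1, dfd)
    lam = dfd * pr2 / (1.0 - pr2)
    with np.errstate(invalid="ignore"):
        power = stats.ncf.sf(fcrit, 1, dfd, lam)
    # central case returned exactly as the nominal level, not via ncf at nc=0
    power = np.where(lam == 0.0, spec.level, power)
    return float(power) if np.ndim(partial_r2) == 0 else power


def bias_curve(
    family: str,
    beta: float,
    gamma: float,
    spec: TestSpec,
    link: Optional[ReliabilityLink] = None,
    grid: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Bias curve over a loading grid: partial R2, derivative, false power.

    ``family`` selects the curve: ``model1`` (loading of the confounder
    surrogate, exposure exact), ``model2_constrained`` (both loadings tied
    equal), or ``omega`` (alpha_x linked to alpha_z through ``link``; the
    grid then runs over alpha_z).  Returns a DataFrame with columns
    ``alpha``, ``partial_r2``, ``derivative``, ``false_power``.  For the
    omega family the derivative is a central finite difference; the other
    two use the exact closed forms.
    """
    if family not in CURVE_FAMILIES:
        raise DomainError(f"unknown curve family {family!r}; choose from {CURVE_FAMILIES}")
    if grid is None:
        grid = analytic.default_alpha_grid()
    grid = np.asarray(grid, dtype=float)

    if family == "model1":
        pr2 = analytic.partial_r2_model1(grid, beta, gamma)
        deriv = analytic.d_partial_r2_model1(grid, beta, gamma)
    elif family == "model2_constrained":
        pr2 = analytic.partial_r2_model2_constrained(grid, beta, gamma)
        deriv = analytic.d_partial_r2_model2_constrained(grid, beta, gamma)
    else:
        if link is None:
            raise DomainError("the omega family requires a ReliabilityLink")
        curve = lambda a: analytic.partial_r2_omega(a, beta, gamma, link)
        pr2 = curve(grid)
        h = 1e-7
        lo = np.clip(grid - h, 0.0, None)
        hi = np.minimum(grid + h, 1.0 - 1e-9)
        deriv = (curve(hi) - curve(lo)) / (hi - lo)

    return pd.DataFrame(
        {
            "alpha": grid,
            "partial_r2": pr2,
            "derivative": deriv,
            "false_power": false_power(pr2, spec),
        }
    )
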