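"""Closed-form squared partial correlations and their calculus.

The population squared partial correlation of outcome and (observed)
exposure given the observed confounder surrogate,

    R2_{Y,X.Z'} = (R2_{Y.X,Z'} - R2_{Y.Z'}) / (1 - R2_{Y.Z'}),

measures residual confounding: under the structural models there is no
direct exposure -> outcome path, so any positive value is spurious
association that survives adjustment because the confounder (and possibly
the exposure) is measured with error.  This module provides

* the generic assembly from any labeled 3x3 correlation matrix,
* the closed forms in the path coefficients for Model 1, Model 2, the
  equal-reliability constrained case, and the affine-linked case
  ``alpha_x = omega * alpha_z + a0`` (with its reduced form for a0 = 0),
* exact first derivatives with respect to the loading ``alpha``,
* critical-point (bisection) and monotonicity analysis of the bias curves.

Every function accepting loadings is vectorized over them via numpy
broadcasting; scalars in give scalars out.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Optional, Union

import numpy as np
from scipy import optimize

from .errors import DomainError, SingularityError
from .path_models import CorrMatrix3, ReliabilityLink

__all__ = [
    "PartialR2Result",
    "CriticalPointResult",
    "r2_full_from_corr",
    "r2_reduced_from_corr",
    "partial_r2",
    "partial_r2_model1",
    "partial_r2_model2",
    "partial_r2_model2_constrained",
    "partial_r2_omega",
    "d_partial_r2_model1",
    "d_partial_r2_model2_constrained",
    "critical_point",
    "classify_monotonicity",
    "default_alpha_grid",
]

#: Denominators closer to zero than this raise SingularityError.
SINGULARITY_TOL = 1e-12

#: Default grid on [0, 1 - GRID_EDGE_EPS] for curve evaluation/classification.
GRID_SIZE = 512
GRID_EDGE_EPS = 1e-6

#: Threshold below which a finite-difference slope counts as zero.
SIGN_TOL = 1e-10

ArrayLike = Union[float, np.ndarray]

Shape = Literal["monotone_decreasing", "monotone_nondecreasing", "unimodal_interior_max"]


@dataclass(frozen=True)
class PartialR2Result:
    """Squared partial correlation with the two R-squareds it is built from."""

    value: float
    r2_full: float
    r2_reduced: float


@dataclass(frozen=True)
class CriticalPointResult:
    """Location of the interior maximum of a bias curve, if it has one."""

    alpha_star: Optional[float]
    shape: Shape


def _validate_loadings(**params: ArrayLike) -> dict[str, np.ndarray]:
    out = {}
    for name, value in params.items():
        arr = np.asarray(value, dtype=float)
        if np.any(~np.isfinite(arr)) or np.any(np.abs(arr) > 1.0):
            raise DomainError(f"{name} outside [-1, 1]")
        out[name] = arr
    return out


def _maybe_scalar(x: np.ndarray) -> ArrayLike:
    return float(x) if np.ndim(x) == 0 else x


def _guard_denominator(den: np.ndarray, what: str) -> None:
    if np.any(np.abs(den) < SINGULARITY_TOL):
        raise SingularityError(
            f"{what} is numerically zero; evaluate at the boundary via an "
            "explicit limit (e.g. alpha = 1 - 1e-8) instead"
        )


def _partial_from_rhos(r_xy: ArrayLike, r_zy: ArrayLike, r_xz: ArrayLike) -> ArrayLike:
    """Squared partial correlation from the three zero-order correlations."""
    r_xy, r_zy, r_xz = (np.asarray(v, dtype=float) for v in (r_xy, r_zy, r_xz))
    den_full = 1.0 - r_xz**2
    den_part = 1.0 - r_zy**2
    _guard_denominator(den_full, "1 - rho(X,Z')^2")
    _guard_denominator(den_part, "1 - rho(Y,Z')^2")
    full = (r_xy**2 + r_zy**2 - 2.0 * r_xy * r_zy * r_xz) / den_full
    return _maybe_scalar((full - r_zy**2) / den_part)


# ---------------------------------------------------------------------------
# Generic assembly from a correlation matrix
# ---------------------------------------------------------------------------


def _rhos(c: CorrMatrix3) -> tuple[float, float, float]:
    """(rho_xy, rho_z'y, rho_xz') with x the middle-labeled variable."""
    zp, x, y = c.labels
    return c.rho(x, y), c.rho(zp, y), c.rho(x, zp)


def r2_full_from_corr(c: CorrMatrix3) -> float:
    """R2 of the regression of Y on both the exposure and Z'.

    ``(rho_xy^2 + rho_z'y^2 - 2 rho_xy rho_z'y rho_xz') / (1 - rho_xz'^2)``.
    """
    r_xy, r_zy, r_xz = _rhos(c)
    den = 1.0 - r_xz**2
    _guard_denominator(np.asarray(den), "1 - rho(X,Z')^2")
    return (r_xy**2 + r_zy**2 - 2.0 * r_xy * r_zy * r_xz) / den


def r2_reduced_from_corr(c: CorrMatrix3) -> float:
    """R2 of the regression of Y on Z' alone: rho(Y,Z')^2."""
    _, r_zy, _ = _rhos(c)
    return r_zy**2


def partial_r2(c: CorrMatrix3) -> PartialR2Result:
    """Squared partial correlation of Y and the exposure controlling for Z'."""
    full = r2_full_from_corr(c)
    reduced = r2_reduced_from_corr(c)
    _guard_denominator(np.asarray(1.0 - reduced), "1 - R2_reduced")
    return PartialR2Result(
        value=(full - reduced) / (1.0 - reduced), r2_full=full, r2_reduced=reduced
    )


# ---------------------------------------------------------------------------
# Closed forms in the path coefficients
# ---------------------------------------------------------------------------


def partial_r2_model1(alpha: ArrayLike, beta: ArrayLike, gamma: ArrayLike) -> ArrayLike:
    """Model-1 squared partial correlation as a function of the loading alpha.

    Substituting the implied correlations (gamma*beta, alpha*beta, gamma*alpha)
    into the generic formula.  At alpha = 1 (perfectly reliable confounder
    measurement) the value is 0; at alpha = 0 it equals (gamma*beta)^2.
    """
    p = _validate_loadings(alpha=alpha, beta=beta, gamma=gamma)
    a, b, g = p["alpha"], p["beta"], p["gamma"]
    return _partial_from_rhos(g * b, a * b, g * a)


def partial_r2_model2(
    alpha_x: ArrayLike, alpha_z: ArrayLike, beta: ArrayLike, gamma: ArrayLike
) -> ArrayLike:
    """Model-2 squared partial correlation with decoupled reliabilities."""
    p = _validate_loadings(alpha_x=alpha_x, alpha_z=alpha_z, beta=beta, gamma=gamma)
    ax, az, b, g = p["alpha_x"], p["alpha_z"], p["beta"], p["gamma"]
    return _partial_from_rhos(ax * g * b, az * b, ax * g * az)


def partial_r2_model2_constrained(
    alpha: ArrayLike, beta: ArrayLike, gamma: ArrayLike
) -> ArrayLike:
    """Model 2 under the equal-reliability constraint alpha_x = alpha_z = alpha.

    This is the tied-reliability case in which the bias curve becomes
    non-monotone in alpha: zero at both endpoints (a useless exposure
    measurement carries no spurious signal; perfect measurements leave no
    residual confounding) and positive in between whenever beta*gamma != 0.
    """
    return partial_r2_model2(alpha, alpha, beta, gamma)


def partial_r2_omega(
    alpha_z: ArrayLike,
    beta: ArrayLike,
    gamma: ArrayLike,
    link: ReliabilityLink,
) -> ArrayLike:
    """Squared partial correlation with alpha_x linked to alpha_z.

    For ``a0 = 0`` uses the reduced closed form

        (alpha_z beta omega gamma)^2 (1 - alpha_z^2 (2 - alpha_z^2))
        -----------------------------------------------------------
         (1 - (omega alpha_z^2 gamma)^2) (1 - (alpha_z beta)^2)

    valid under ``omega < 1 / (gamma alpha_z^2)``; for ``a0 != 0`` it
    substitutes alpha_x = omega*alpha_z + a0 into the Model-2 form directly.
    """
    p = _validate_loadings(alpha_z=alpha_z, beta=beta, gamma=gamma)
    az, b, g = p["alpha_z"], p["beta"], p["gamma"]
    ax = link.alpha_x(az)
    if link.a0 != 0.0:
        if np.any(np.abs(ax) > 1.0):
            raise DomainError(
                f"linked alpha_x = {link.omega}*alpha_z + {link.a0} leaves [-1, 1]"
            )
        return partial_r2_model2(ax, az, b, g)
    # reduced closed form; guard the constraint omega < 1/(gamma alpha_z^2)
    # (checked before the alpha_x range so a violating omega is reported
    # against the bound that makes the reduced form invalid)
    s = az**2
    bound = g * s
    if np.any((np.asarray(bound) > 0) & (link.omega * np.asarray(bound) >= 1.0)):
        raise DomainError(
            f"omega={link.omega} violates omega < 1/(gamma*alpha_z^2); the "
            "reduced closed form is not valid there"
        )
    if np.any(np.abs(ax) > 1.0):
        raise DomainError(
            f"linked alpha_x = {link.omega}*alpha_z leaves [-1, 1]"
        )
    # the numerator factor 1 - az^2 (2 - az^2) is written as (1 - az^2)^2 and
    # the first denominator factor as a difference of squares: identical
    # algebra, but free of the catastrophic cancellation near az = 1 that the
    # expanded forms suffer (the half limit needs ~1e-12 accuracy there)
    t = 1.0 - s
    c = link.omega * s * g
    den1 = (1.0 - c) * (1.0 + c)
    den2 = 1.0 - (az * b) ** 2
    _guard_denominator(np.asarray(den1), "1 - rho(X',Z')^2")
    _guard_denominator(np.asarray(den2), "1 - rho(Y,Z')^2")
    num = s * (b * link.omega * g) ** 2 * t**2
    return _maybe_scalar(num / (den1 * den2))


# ---------------------------------------------------------------------------
# First derivatives with respect to alpha
# ---------------------------------------------------------------------------


def d_partial_r2_model1(alpha: ArrayLike, beta: ArrayLike, gamma: ArrayLike) -> ArrayLike:
    """d/d(alpha) of the Model-1 curve.

    ``2a(a^2-1) b^2 g^2 [2 - (1+a^2)g^2 + b^2(-1 + a^2(-1 + 2g^2))]
    / [(a^2 b^2 - 1)^2 (a^2 g^2 - 1)^2]``.

    Negative on (0, 1) for every beta, gamma in (-1, 1)\\{0}: better confounder
    measurement always means less residual confounding.  Odd in alpha.
    """
    p = _validate_loadings(alpha=alpha, beta=beta, gamma=gamma)
    a, b, g = p["alpha"], p["beta"], p["gamma"]
    den = (-1.0 + a**2 * b**2) ** 2 * (-1.0 + a**2 * g**2) ** 2
    _guard_denominator(np.asarray(den), "derivative denominator")
    bracket = 2.0 - (1.0 + a**2) * g**2 + b**2 * (-1.0 + a**2 * (-1.0 + 2.0 * g**2))
    return _maybe_scalar(2.0 * a * (-1.0 + a**2) * b**2 * g**2 * bracket / den)


def _constrained_derivative_poly(
    alpha: ArrayLike, beta: ArrayLike, gamma: ArrayLike
) -> np.ndarray:
    """Bracketed polynomial factor of the constrained Model-2 derivative.

    -1 + 3a^2 + a^6 (2b^2 - 1) g^2 - a^4 (2b^2 + g^2).  Its unique root in
    (0, 1) is the critical point; the prefactor 2a(a^2-1)b^2g^2 never
    vanishes there, so roots of the derivative and of this factor coincide.
    """
    a = np.asarray(alpha, dtype=float)
    b = np.asarray(beta, dtype=float)
    g = np.asarray(gamma, dtype=float)
    return -1.0 + 3.0 * a**2 + a**6 * (-1.0 + 2.0 * b**2) * g**2 - a**4 * (2.0 * b**2 + g**2)


def d_partial_r2_model2_constrained(
    alpha: ArrayLike, beta: ArrayLike, gamma: ArrayLike
) -> ArrayLike:
    """d/d(alpha) of the equal-reliability Model-2 curve.

    ``2a(a^2-1) b^2 g^2 p(a) / [(a^2 b^2 - 1)^2 (a^4 g^2 - 1)^2]`` with
    ``p`` the polynomial of :func:`_constrained_derivative_poly`.
    """
    p = _validate_loadings(alpha=alpha, beta=beta, gamma=gamma)
    a, b, g = p["alpha"], p["beta"], p["gamma"]
    den = (-1.0 + a**2 * b**2) ** 2 * (-1.0 + a**4 * g**2) ** 2
    _guard_denominator(np.asarray(den), "derivative denominator")
    poly = _constrained_derivative_poly(a, b, g)
    return _maybe_scalar(2.0 * a * (-1.0 + a**2) * b**2 * g**2 * poly / den)


# ---------------------------------------------------------------------------
# Critical point and shape classification
# ---------------------------------------------------------------------------


def critical_point(beta: float, gamma: float) -> CriticalPointResult:
    """Interior maximizer of the equal-reliability bias curve.

    Bisects the bracketed polynomial factor of the derivative on
    (1e-6, 1 - 1e-6) to |alpha| tolerance 1e-12.  The analysis is restricted
    to alpha > 0; the curve is even in alpha so -alpha_star is the mirror
    critical point.  If the factor has no sign change on the interval the
    curve is classified by shape instead of returning a root.
    """
    if not (0.0 < beta < 1.0 and 0.0 < gamma < 1.0):
        raise DomainError("critical_point requires beta, gamma in (0, 1)")
    lo, hi = 1e-6, 1.0 - 1e-6
    f = lambda a: float(_constrained_derivative_poly(a, beta, gamma))
    if f(lo) * f(hi) > 0:
        shape = classify_monotonicity(
            lambda a: partial_r2_model2_constrained(a, beta, gamma), GRID_SIZE
        )
        return CriticalPointResult(alpha_star=None, shape=shape)
    root = optimize.bisect(f, lo, hi, xtol=1e-12)
    return CriticalPointResult(alpha_star=float(root), shape="unimodal_interior_max")


def default_alpha_grid(grid_size: int = GRID_SIZE, upper: float = 1.0 - GRID_EDGE_EPS) -> np.ndarray:
    """Uniform loading grid on [0, upper] used for curves and classification."""
    return np.linspace(0.0, upper, grid_size)


def classify_monotonicity(
    curve_fn: Callable[[np.ndarray], np.ndarray], grid_size: int = GRID_SIZE
) -> Shape:
    """Classify a bias curve on [0, 1) from finite-difference slope signs.

    Slopes with magnitude below SIGN_TOL count as zero.  A curve whose
    nonzero slopes change sign more than once is rejected outright: no curve
    in this family does that, so it indicates a formula error upstream.
    """
    grid = default_alpha_grid(grid_size)
    values = np.asarray(curve_fn(grid), dtype=float)
    slopes = np.diff(values) / np.diff(grid)
    signs = np.where(slopes > SIGN_TOL, 1, np.where(slopes < -SIGN_TOL, -1, 0))
    nonzero = signs[signs != 0]
    if nonzero.size == 0 or np.all(nonzero >= 0):
        return "monotone_nondecreasing"
    if np.all(nonzero <= 0):
        return "monotone_decreasing"
    changes = np.nonzero(np.diff(nonzero))[0]
    if changes.size == 1 and nonzero[0] > 0:
        return "unimodal_interior_max"
    raise DomainError(
        "curve shape is neither monotone nor unimodal-with-interior-max; "
        "this family should not produce such a shape"
    )
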