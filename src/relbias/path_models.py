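"""Standardized path models with error-prone measurements.

Two structural models for testing an exposure--outcome association while
adjusting for a confounder measured with error, under the classical
true-score model (observed = loading x true + independent noise):

* Model 1 -- one error-prone measurement.  The latent confounder ``Z`` drives
  both the outcome ``Y`` (path ``beta``) and the exposure ``X`` (path
  ``gamma``); only an error-prone surrogate ``Z' = alpha Z + e`` is observed.
  There is no direct ``X -> Y`` path, so any partial association of ``X`` and
  ``Y`` given ``Z'`` is residual confounding.

* Model 2 -- two error-prone measurements.  As Model 1, but the exposure is
  also observed through a surrogate ``X' = alpha_x X + e_x`` while the
  confounder surrogate is ``Z' = alpha_z Z + e_z``.

All variables are standardized: ``Z ~ N(0, 1)`` and every error variance is
chosen so that ``Y``, ``X``, ``X'`` and ``Z'`` each have unit variance.  A
loading ``alpha`` therefore carries reliability ``alpha**2`` (the proportion
of observed variance attributable to the true score), and implied
correlations are products of path coefficients along connecting paths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Union

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "PathModel1",
    "PathModel2",
    "ReliabilityLink",
    "CorrMatrix3",
    "implied_corr_model1",
    "implied_corr_model2",
    "error_variances",
]


def _check_loading(name: str, value: float) -> float:
    """Validate a standardized path coefficient.

    The closed interval [-1, 1] is admitted: interior values are the generic
    case, while the boundary (zero error variance, e.g. a perfectly reliable
    measurement) is a legitimate degenerate member of the family and is
    needed for the no-measurement-error calibration endpoints.
    """
    value = float(value)
    if not np.isfinite(value) or abs(value) > 1.0:
        raise DomainError(
            f"{name}={value!r} outside [-1, 1]; standardized path "
            "coefficients must have magnitude at most 1"
        )
    return value


@dataclass(frozen=True)
class PathModel1:
    """One error-prone confounder: Y = beta Z + eps_y, X = gamma Z + eps_x,
    Z' = alpha Z + e, with Z ~ N(0,1). Reliability of Z' is alpha**2."""

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma"):
            object.__setattr__(self, name, _check_loading(name, getattr(self, name)))


@dataclass(frozen=True)
class PathModel2:
    """Both measurements error-prone: additionally X' = alpha_x X + e_x and
    Z' = alpha_z Z + e_z. Reliabilities are alpha_x**2 and alpha_z**2."""

    alpha_x: float
    alpha_z: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        for name in ("alpha_x", "alpha_z", "beta", "gamma"):
            object.__setattr__(self, name, _check_loading(name, getattr(self, name)))


@dataclass(frozen=True)
class ReliabilityLink:
    """Affine link tying the exposure loading to the confounder loading,
    ``alpha_x = omega * alpha_z + a0``.

    With ``a0 = 0`` the squared partial correlation admits a reduced closed
    form valid when ``omega < 1 / (gamma * alpha_z**2)``; the link is useful
    because tying the two reliabilities together (e.g. ``omega = 1``,
    the equal-reliability constraint) is exactly what makes bias non-monotone
    in reliability.
    """

    omega: float
    a0: float = 0.0

    def alpha_x(self, alpha_z: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
        return self.omega * np.asarray(alpha_z, dtype=float) + self.a0


@dataclass(frozen=True)
class CorrMatrix3:
    """A labeled 3x3 correlation matrix over (Z', X or X', Y).

    The fixed variable ordering prevents index mistakes when the matrix is
    consumed by the partial-correlation formulas downstream.
    """

    labels: tuple[str, str, str]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (3, 3):
            raise DomainError(f"expected a 3x3 matrix, got shape {vals.shape}")
        if not np.allclose(vals, vals.T, atol=1e-12):
            raise DomainError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(vals), 1.0, atol=1e-12):
            raise DomainError("correlation matrix must have unit diagonal")
        off = vals[~np.eye(3, dtype=bool)]
        if np.any(np.abs(off) > 1.0 + 1e-12):
            raise DomainError("off-diagonal correlations must lie in [-1, 1]")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "values", vals)

    def rho(self, a: str, b: str) -> float:
        """Correlation between the variables labeled ``a`` and ``b``."""
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def is_psd(self, tol: float = 1e-10) -> bool:
        return bool(np.linalg.eigvalsh(self.values).min() >= -tol)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="")


def implied_corr_model1(m: PathModel1) -> CorrMatrix3:
    """Correlation matrix over (Z', X, Y) implied by Model 1.

    By the tracing rules of path analysis: rho(X, Z') = gamma * alpha,
    rho(Z', Y) = alpha * beta, rho(X, Y) = gamma * beta.
    """
    r_xz = m.gamma * m.alpha
    r_zy = m.alpha * m.beta
    r_xy = m.gamma * m.beta
    vals = np.array([[1.0, r_xz, r_zy], [r_xz, 1.0, r_xy], [r_zy, r_xy, 1.0]])
    return CorrMatrix3(labels=("Z'", "X", "Y"), values=vals)


def implied_corr_model2(m: PathModel2) -> CorrMatrix3:
    """Correlation matrix over (Z', X', Y) implied by Model 2.

    rho(X', Z') = alpha_x * gamma * alpha_z, rho(Z', Y) = beta * alpha_z,
    rho(X', Y) = beta * gamma * alpha_x.  Note that every observed
    correlation is attenuated by the loadings of the surrogates involved.
    """
    r_xz = m.alpha_x * m.gamma * m.alpha_z
    r_zy = m.beta * m.alpha_z
    r_xy = m.beta * m.gamma * m.alpha_x
    vals = np.array([[1.0, r_xz, r_zy], [r_xz, 1.0, r_xy], [r_zy, r_xy, 1.0]])
    return CorrMatrix3(labels=("Z'", "X'", "Y"), values=vals)


def error_variances(m: Union[PathModel1, PathModel2]) -> Mapping[str, float]:
    """Error-term variances that standardize every observed variable.

    For Model 1: var(eps_y) = 1 - beta**2, var(eps_x) = 1 - gamma**2,
    var(e) = 1 - alpha**2.  Model 2 splits the measurement error into
    e_z and e_x with variances 1 - alpha_z**2 and 1 - alpha_x**2.
    """
    if isinstance(m, PathModel1):
        return {
            "eps_y": 1.0 - m.beta**2,
            "eps_x": 1.0 - m.gamma**2,
            "e": 1.0 - m.alpha**2,
        }
    if isinstance(m, PathModel2):
        return {
            "eps_y": 1.0 - m.beta**2,
            "eps_x": 1.0 - m.gamma**2,
            "e_z": 1.0 - m.alpha_z**2,
            "e_x": 1.0 - m.alpha_x**2,
        }
    raise TypeError(f"expected PathModel1 or PathModel2, got {type(m).__name__}")
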