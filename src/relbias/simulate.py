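"""Monte Carlo engine for the path models.

Generates finite samples directly from the structural equations (latent
confounder Z ~ N(0,1), all error terms independent normals with the
standardizing variances), runs the adjusted OLS test of the exposure on
each replicate, and estimates the rejection rate with its binomial standard
error.  This is the empirical check on every closed-form claim in
:mod:`relbias.analytic` and :mod:`relbias.inference`.

Replicate streams are spawned from a single user seed via
``numpy.random.SeedSequence``: results are bit-reproducible for a given
seed and independent of how replicates are chunked internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError
from .path_models import PathModel1, PathModel2, error_variances

__all__ = ["SimConfig", "SimResult", "draw_sample", "fit_partial_test", "rejection_rate"]

#: Replicates per internal chunk; bounds peak memory at ~5 * CHUNK * n floats.
_CHUNK = 2000


@dataclass(frozen=True)
class SimConfig:
    """One Monte Carlo experiment: model, sample size, replicates, seed, level."""

    model: Union[PathModel1, PathModel2]
    n: int
    reps: int
    seed: int
    level: float = 0.05
    #: "ols" rejects on the standard partial t test; "paper_f" rejects on the
    #: partial-correlation F expression rho_p_hat^2 * (n - 3) against the same
    #: central-F critical value (provided for comparison with the printed form).
    statistic: str = "ols"

    def __post_init__(self) -> None:
        if self.n < 5:
            raise DomainError("n must be >= 5 (residual df >= 2)")
        if self.reps < 1:
            raise DomainError("reps must be >= 1")
        if not (0.0 < self.level < 1.0):
            raise DomainError("level must lie in (0, 1)")
        if self.statistic not in ("ols", "paper_f"):
            raise DomainError("statistic must be 'ols' or 'paper_f'")


@dataclass(frozen=True)
class SimResult:
    """Monte Carlo rejection rate with uncertainty."""

    rejection_rate: float
    mc_se: float
    mean_partial_r2: float
    reps_used: int

    def to_dict(self) -> dict:
        return {
            "rejection_rate": self.rejection_rate,
            "mc_se": self.mc_se,
            "mean_partial_r2": self.mean_partial_r2,
            "reps_used": self.reps_used,
        }


def _draw_arrays(
    model: Union[PathModel1, PathModel2],
    n: int,
    reps: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(Y, observed exposure, Z') arrays of shape (reps, n) from the paths."""
    ev = error_variances(model)
    z = rng.standard_normal((reps, n))
    y = model.beta * z + np.sqrt(ev["eps_y"]) * rng.standard_normal((reps, n))
    x = model.gamma * z + np.sqrt(ev["eps_x"]) * rng.standard_normal((reps, n))
    if isinstance(model, PathModel1):
        zp = model.alpha * z + np.sqrt(ev["e"]) * rng.standard_normal((reps, n))
        xobs = x
    else:
        zp = model.alpha_z * z + np.sqrt(ev["e_z"]) * rng.standard_normal((reps, n))
        xobs = model.alpha_x * x + np.sqrt(ev["e_x"]) * rng.standard_normal((reps, n))
    return y, xobs, zp


def draw_sample(
    model: Union[PathModel1, PathModel2], n: int, seed: int
) -> pd.DataFrame:
    """One sample of size n; columns Y, X (or X'), Z' per the path equations."""
    if n < 1:
        raise DomainError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    y, xobs, zp = _draw_arrays(model, n, 1, rng)
    xlabel = "X" if isinstance(model, PathModel1) else "X'"
    return pd.DataFrame({"Y": y[0], xlabel: xobs[0], "Z'": zp[0]})


def _partial_t(
    y: np.ndarray, x: np.ndarray, z: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized partial t test of x in OLS of y on (1, x, z), rowwise.

    Works through sample correlations: the t statistic of the x coefficient
    equals r_p * sqrt(n-3) / sqrt(1 - r_p^2) with r_p the sample partial
    correlation of y and x given z.  Returns (t, r_p^2).
    """
    n = y.shape[-1]

    def corr(u, v):
        uc = u - u.mean(axis=-1, keepdims=True)
        vc = v - v.mean(axis=-1, keepdims=True)
        num = (uc * vc).sum(axis=-1)
        den = np.sqrt((uc**2).sum(axis=-1) * (vc**2).sum(axis=-1))
        if np.any(den == 0.0):
            raise DomainError("singular design: a column is constant")
        return num / den

    r_xy, r_zy, r_xz = corr(x, y), corr(z, y), corr(x, z)
    den = (1.0 - r_zy**2) * (1.0 - r_xz**2)
    if np.any(den <= 0.0):
        raise DomainError("singular design: perfectly collinear columns")
    r_p = (r_xy - r_zy * r_xz) / np.sqrt(den)
    r_p = np.clip(r_p, -1.0 + 1e-15, 1.0 - 1e-15)
    t = r_p * np.sqrt(n - 3) / np.sqrt(1.0 - r_p**2)
    return t, r_p**2


def fit_partial_test(
    sample: pd.DataFrame, level: float = 0.05
) -> tuple[float, float, bool]:
    """Adjusted test of the exposure on one sample.

    OLS of the first column (Y) on the remaining two (exposure, Z') with
    intercept; two-sided test of the exposure coefficient.  Returns the
    sample squared partial correlation t^2/(t^2 + n - 3), the p-value, and
    the rejection flag at ``level``.
    """
    arr = np.asarray(sample, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise DomainError("sample must have exactly three columns (Y, exposure, Z')")
    n = arr.shape[0]
    if n < 5:
        raise DomainError("need n >= 5 observations")
    y, x, z = arr[:, 0], arr[:, 1], arr[:, 2]
    t, pr2 = _partial_t(y, x, z)
    pval = 2.0 * stats.t.sf(abs(float(t)), n - 3)
    return float(pr2), float(pval), bool(pval < level)


def rejection_rate(cfg: SimConfig) -> SimResult:
    """Monte Carlo rejection rate of the adjusted test under ``cfg``.

    Replicates are processed in chunks, each drawn from its own spawned
    child of ``SeedSequence(cfg.seed)``, so results do not depend on chunk
    size.  The standard error is the binomial sqrt(r(1-r)/reps).
    """
    n, reps = cfg.n, cfg.reps
    dfd = n - 3
    children = np.random.SeedSequence(cfg.seed).spawn((reps + _CHUNK - 1) // _CHUNK)
    fcrit = stats.f.ppf(1.0 - cfg.level, 1, dfd)

    rejected = 0
    pr2_sum = 0.0
    done = 0
    for child in children:
        m = min(_CHUNK, reps - done)
        rng = np.random.default_rng(child)
        y, xobs, zp = _draw_arrays(cfg.model, n, m, rng)
        t, pr2 = _partial_t(y, xobs, zp)
        if cfg.statistic == "ols":
            rejected += int(np.count_nonzero(t**2 > fcrit))
        else:
            rejected += int(np.count_nonzero(pr2 * dfd > fcrit))
        pr2_sum += float(pr2.sum())
        done += m
    rate = rejected / reps
    return SimResult(
        rejection_rate=rate,
        mc_se=float(np.sqrt(rate * (1.0 - rate) / reps)),
        mean_partial_r2=pr2_sum / reps,
        reps_used=reps,
    )
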