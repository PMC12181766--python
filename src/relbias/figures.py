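"""Reproduction of the four bias-curve figures.

Each figure is rendered from the analytic module on a deterministic grid
and written as a PNG *plus* a CSV of the underlying numbers, so the curves
are regression-testable without image comparison.  Parameter sets are fixed
to the canonical examples:

* ``fig2`` — Model-1 curve, gamma = 0.64, beta = 0.13: squared partial
  correlation strictly decreasing in the confounder loading alpha.
* ``fig4`` — equal-reliability Model-2 curve, gamma = 0.19, beta = 0.50:
  unimodal with interior maximum at the critical point alpha*.
* ``fig5`` — linked-reliability curve (omega = -1, a0 = 0) with
  beta = gamma = 1: non-decreasing in alpha_z, approaching 1/2.
* ``fig6`` — first derivative of the fig5 curve.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .errors import DomainError
from .path_models import ReliabilityLink
from . import analytic
from .inference import TestSpec, bias_curve
from ._version import version_line

__all__ = ["FIGURES", "render_figure"]

#: fig5/fig6 evaluate alpha_z up to 0.999 (the half limit is approached but
#: never attained; beta = gamma = 1 makes alpha_z = 1 a true singularity).
_OMEGA_GRID_UPPER = 0.999

FIGURES: dict[str, dict] = {
    "fig2": {"family": "model1", "beta": 0.13, "gamma": 0.64},
    "fig4": {"family": "model2_constrained", "beta": 0.50, "gamma": 0.19},
    "fig5": {"family": "omega", "beta": 1.0, "gamma": 1.0, "omega": -1.0, "a0": 0.0},
    "fig6": {
        "family": "omega",
        "beta": 1.0,
        "gamma": 1.0,
        "omega": -1.0,
        "a0": 0.0,
        "plot": "derivative",
    },
}


def render_figure(
    fig_id: str,
    out_dir: str | Path = ".",
    grid_size: int = analytic.GRID_SIZE,
    n: int = 1000,
    level: float = 0.05,
) -> tuple[Path, Path]:
    """Render one figure; returns (png_path, csv_path).

    The CSV carries columns alpha, partial_r2, derivative, false_power
    (false power computed at sample size ``n``), preceded by a ``#`` header
    line recording the full parameter set for provenance.
    """
    if fig_id not in FIGURES:
        raise DomainError(f"unknown figure id {fig_id!r}; choose from {sorted(FIGURES)}")
    spec = FIGURES[fig_id]
    family, beta, gamma = spec["family"], spec["beta"], spec["gamma"]
    link: Optional[ReliabilityLink] = None
    grid = analytic.default_alpha_grid(grid_size)
    if family == "omega":
        link = ReliabilityLink(omega=spec["omega"], a0=spec["a0"])
        grid = np.linspace(0.0, _OMEGA_GRID_UPPER, grid_size)

    curve = bias_curve(family, beta, gamma, TestSpec(n=n, level=level), link=link, grid=grid)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{fig_id}.csv"
    png_path = out_dir / f"{fig_id}.png"

    params = {k: v for k, v in spec.items() if k != "plot"}
    header = f"# {version_line()} {fig_id} params={params} n={n} level={level} grid_size={grid_size}\n"
    with open(csv_path, "w") as fh:
        fh.write(header)
        curve.to_csv(fh, index=False, lineterminator="\n")

    ycol = spec.get("plot", "partial_r2")
    xlabel = r"$\alpha_z$" if family == "omega" else r"$\alpha$"
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["alpha"], curve[ycol], lw=1.5)
    ax.set_xlabel(xlabel + " (square root of reliability)")
    if ycol == "derivative":
        ax.set_ylabel("d(squared partial correlation)/d" + xlabel)
    else:
        ax.set_ylabel("squared partial correlation")
    if fig_id == "fig4":
        cp = analytic.critical_point(beta, gamma)
        ax.axvline(cp.alpha_star, ls="--", color="gray", lw=1)
        ax.annotate(
            rf"$\alpha^*={cp.alpha_star:.3f}$",
            xy=(cp.alpha_star, float(curve["partial_r2"].max())),
            xytext=(cp.alpha_star + 0.03, float(curve["partial_r2"].max()) * 0.95),
        )
    ax.set_title(f"{fig_id}: {family}, " + ", ".join(f"{k}={v}" for k, v in params.items() if k != "family"))
    fig.tight_layout()
    fig.savefig(png_path, dpi=150)
    plt.close(fig)
    return png_path, csv_path
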