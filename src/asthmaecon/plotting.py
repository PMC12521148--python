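"""Cost-effectiveness plane and acceptability-curve plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Ellipse

from .psa import EllipseSummary, PSAResult, ce_plane_summary

__all__ = ["plot_ce_plane", "plot_ceac"]


def plot_ce_plane(
    result: PSAResult,
    summary: EllipseSummary | None = None,
    wtp: float | None = None,
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """Scatter of (dU, dC) draws with the confidence ellipse.

    The x-axis is the incremental utility (QALYs) and the y-axis the
    incremental cost (CNY); a dashed line marks the willingness-to-pay
    threshold when given.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(result.delta_utility, result.delta_cost, s=6, alpha=0.4, lw=0)
    if summary is None and result.n_iterations >= 3:
        summary = ce_plane_summary(result)
    if summary is not None and not summary.degenerate:
        ell = Ellipse(
            xy=summary.center,
            width=2 * summary.axes[0],
            height=2 * summary.axes[1],
            angle=summary.angle_deg,
            fill=False,
            color="crimson",
            lw=1.5,
            label=f"{summary.confidence:.0%} ellipse",
        )
        ax.add_patch(ell)
    if wtp is not None:
        xs = np.array(ax.get_xlim())
        ax.plot(xs, wtp * xs, ls="--", color="gray", lw=1, label="WTP threshold")
    ax.axhline(0, color="black", lw=0.6)
    ax.axvline(0, color="black", lw=0.6)
    ax.set_xlabel("Incremental utility (QALYs)")
    ax.set_ylabel("Incremental cost (CNY)")
    ax.set_title(f"{result.alt_label} vs {result.ref_label}")
    ax.legend(loc="best", fontsize=8)
    return ax


def plot_ceac(
    grid: np.ndarray,
    prob: np.ndarray,
    wtp: float | None = None,
    ax: plt.Axes | None = None,
    label: str | None = None,
) -> plt.Axes:
    """Cost-effectiveness acceptability curve over the WTP grid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(grid, prob, lw=1.5, label=label)
    if wtp is not None:
        ax.axvline(wtp, ls="--", color="gray", lw=1)
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("Willingness to pay (CNY/QALY)")
    ax.set_ylabel("P(cost-effective)")
    if label:
        ax.legend(loc="best", fontsize=8)
    return ax


def save_figure(ax: plt.Axes, path: str | Path) -> Path:
    path = Path(path)
    ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(ax.figure)
    return path
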