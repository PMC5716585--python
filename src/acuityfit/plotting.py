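"""Per-subject psychometric plots: data points, fitted curve, threshold bar."""

from __future__ import annotations

import math

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .fitting import THRESHOLD_LEVEL, FitResult, fit_ml
from .observer import ChoiceData, performance_axis, psi

__all__ = ["plot_subject_fit"]


def plot_subject_fit(
    data: ChoiceData,
    fit: FitResult | None = None,
    *,
    level: float = THRESHOLD_LEVEL,
    path=None,
    ax=None,
):
    """Correct fraction vs spatial frequency with the fitted curve overlaid.

    Filled circles are the observed per-frequency proportions; the line is
    the fitted Weibull evaluated on the reversed performance axis; the red
    bar marks the interpolated threshold where the curve crosses ``level``.
    Saves to ``path`` if given, otherwise returns the axes.
    """
    if fit is None:
        fit = fit_ml(data, level=level)
    own_fig = ax is None
    if own_fig:
        fig, ax = plt.subplots(figsize=(4.5, 3.2))

    f = data.frequencies
    ax.plot(f, data.n_correct / data.n_total, "ko", ms=5, label="observed")
    if fit.params is not None:
        grid = np.linspace(f.min(), fit.axis_origin, 200)
        curve = psi(performance_axis(grid, fit.axis_origin), fit.params)
        ax.plot(grid, curve, "k-", lw=1.2, label="Weibull fit")
    if math.isfinite(fit.threshold_cpd):
        ax.plot([fit.threshold_cpd] * 2, [0.45, level], "r-", lw=2.5)
        ax.annotate(
            f"{fit.threshold_cpd:.1f} cpd", (fit.threshold_cpd, 0.47),
            textcoords="offset points", xytext=(4, 0), color="r", fontsize=8,
        )
    ax.axhline(0.5, color="0.7", lw=0.8, ls=":")
    ax.axhline(level, color="0.7", lw=0.8, ls="--")
    ax.set_xlabel("spatial frequency (cpd)")
    ax.set_ylabel("fraction correct")
    ax.set_ylim(0.3, 1.02)
    ax.set_title(f"{data.subject_id} ({data.species}, {data.condition})", fontsize=9)
    if own_fig:
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
            return None
    return ax
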