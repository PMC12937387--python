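"""Diagnostic and simulation plots (matplotlib).

Figure layout mirrors conventional pharmacometric reporting: per-channel
goodness-of-fit panels (observed vs population/individual predictions,
CWRES vs prediction and vs time, with LOESS trend lines), pc-VPC ribbons,
and PTA-vs-CLcr line plots.  All functions return the figure; pass ``path``
to also write an image file.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diagnostics import VPCResult
from .pkmodel import SERUM, TISSUE
from .pta import PTAGrid

__all__ = ["gof_plots", "vpc_plot", "pta_plot"]

_LOESS_FRAC = 0.75  # span of the LOESS trend lines in residual panels


def _loess(x: np.ndarray, y: np.ndarray):
    from statsmodels.nonparametric.smoothers_lowess import lowess

    if len(x) < 5:
        return None
    sm = lowess(y, x, frac=_LOESS_FRAC, return_sorted=True)
    return sm[:, 0], sm[:, 1]


def gof_plots(cwres_table: pd.DataFrame, path: str | None = None):
    """Goodness-of-fit panel grid from a CWRES table (one row per channel)."""
    import matplotlib.pyplot as plt

    channels = [c for c in (SERUM, TISSUE) if (cwres_table["channel"] == c).any()]
    fig, axes = plt.subplots(len(channels), 4, figsize=(16, 4 * len(channels)), squeeze=False)
    for row, channel in enumerate(channels):
        sub = cwres_table[cwres_table["channel"] == channel]
        label = "unbound serum" if channel == SERUM else "periprostatic tissue"
        for col, (xcol, ycol, xl, yl, identity) in enumerate(
            [
                ("pred", "dv", "population predicted (mg/L)", "observed (mg/L)", True),
                ("ipred", "dv", "individual predicted (mg/L)", "observed (mg/L)", True),
                ("pred", "cwres", "population predicted (mg/L)", "CWRES", False),
                ("time", "cwres", "time after first dose (h)", "CWRES", False),
            ]
        ):
            ax = axes[row, col]
            ax.plot(sub[xcol], sub[ycol], "o", ms=4, alpha=0.6)
            if identity:
                lim = [0, max(sub[xcol].max(), sub[ycol].max()) * 1.05]
                ax.plot(lim, lim, "k--", lw=1)
            else:
                ax.axhline(0.0, color="k", ls="--", lw=1)
                sm = _loess(sub[xcol].to_numpy(), sub[ycol].to_numpy())
                if sm is not None:
                    ax.plot(*sm, color="C3", lw=1.5)
            ax.set_xlabel(xl)
            ax.set_ylabel(yl)
            if col == 0:
                ax.set_title(label, loc="left")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig


def vpc_plot(result: VPCResult, path: str | None = None):
    """pc-VPC ribbons: observed percentiles over simulated 95% bands."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    styles = ["--", "-", "--"]
    for k, pct in enumerate(result.percentiles):
        ax.fill_between(
            result.bin_mid, result.ci_lower[:, k], result.ci_upper[:, k],
            alpha=0.25, color="C0" if k == 1 else "C1", linewidth=0,
        )
        ax.plot(result.bin_mid, result.observed[:, k], styles[k], color="k",
                label=f"observed {pct:g}th")
    ax.set_xlabel("time after first dose (h)")
    ax.set_ylabel("prediction-corrected concentration (mg/L)")
    ax.set_title(f"pc-VPC ({result.channel}, {result.n_replicates} replicates)")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig


def pta_plot(grid: PTAGrid, path: str | None = None):
    """PTA against CLcr, one line per evaluation time, one panel per channel."""
    import matplotlib.pyplot as plt

    channels = list(grid.probability)
    fig, axes = plt.subplots(1, len(channels), figsize=(6 * len(channels), 4.5), squeeze=False)
    for k, channel in enumerate(channels):
        ax = axes[0, k]
        for j, t in enumerate(grid.times):
            ax.plot(grid.clcr, grid.probability[channel][:, j], marker="o", ms=3,
                    label=f"{t:g} h")
        ax.axhline(0.9, color="k", ls=":", lw=1)
        ax.set_xlabel("creatinine clearance (mL/min)")
        ax.set_ylabel("probability of target attainment")
        ax.set_ylim(-0.02, 1.02)
        ax.set_title("unbound serum" if channel == SERUM else "periprostatic tissue")
        ax.legend(title="time after dose")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig
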