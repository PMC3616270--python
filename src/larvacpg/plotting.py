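"""Optional static plots: sweep heatmaps and trajectory traces.

matplotlib is imported lazily so the core package has no hard plotting
dependency.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .experiments import SweepGrid
from .integrator import Trajectory

__all__ = ["plot_sweep_heatmap", "plot_traces"]


def plot_sweep_heatmap(
    grid: SweepGrid,
    value: str,
    path: str | Path | None = None,
    cmap: str = "viridis",
    mask_zero: bool = True,
):
    """Heatmap of one per-cell value of a 2-axis sweep.

    Cells with the 0/no-wave sentinel are shown in grey when
    ``mask_zero`` is set.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = grid.pivot(value)
    data = np.ma.masked_where(mask_zero & (mat.to_numpy() == 0), mat.to_numpy())
    fig, ax = plt.subplots(figsize=(5, 4))
    cm = plt.get_cmap(cmap).copy()
    cm.set_bad("0.7")
    im = ax.pcolormesh(mat.columns, mat.index, data, cmap=cm, shading="nearest")
    fig.colorbar(im, ax=ax, label=value)
    ax.set_xlabel(mat.columns.name)
    ax.set_ylabel(mat.index.name)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_traces(
    trajectory: Trajectory,
    path: str | Path | None = None,
    threshold: float | None = 0.3,
    side: str | None = None,
):
    """Stacked excitatory traces per segment, posterior at the bottom."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    E = trajectory.excitatory(side)
    n = E.shape[1]
    fig, axes = plt.subplots(n, 1, sharex=True, figsize=(6, 1.0 * n))
    for i, ax in enumerate(axes):
        seg = n - 1 - i  # A8 plotted last (bottom)
        ax.plot(trajectory.times, E[:, seg], lw=0.9, color="C0")
        if threshold is not None:
            ax.axhline(threshold, ls="--", lw=0.6, color="0.5")
        ax.set_ylabel(f"E{seg + 1}", rotation=0, labelpad=14, va="center")
        ax.set_ylim(-0.05, 0.7)
    axes[-1].set_xlabel("time (t.u.)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
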