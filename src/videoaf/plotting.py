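"""Focal-trajectory plots: focal path on top, error over time below.

Both panels apply the 5-frame centred moving average used for
visualisation; summary statistics are always computed on the raw series.
"""

from __future__ import annotations

import numpy as np

from .evaluation import EvalResult, IN_FOCUS_THRESHOLD, smooth_trajectory

__all__ = ["plot_trajectories"]


def plot_trajectories(
    results: dict[str, EvalResult],
    window: int = 5,
    threshold: float = IN_FOCUS_THRESHOLD,
    axes=None,
):
    """Overlay focal paths and errors for several policies on one scan.

    ``results`` maps policy name to an :class:`EvalResult` from the same
    scan; the optimal focal power (black) is taken from the first entry.
    """
    import matplotlib.pyplot as plt

    if not results:
        raise ValueError("no results to plot")
    if axes is None:
        _, axes = plt.subplots(2, 1, sharex=True, figsize=(8, 5))
    ax_path, ax_err = axes
    first = next(iter(results.values()))
    t = np.arange(len(first.fstar))
    ax_path.plot(t, smooth_trajectory(first.fstar, window), "k-", label="optimal")
    for name, res in results.items():
        ax_path.plot(t, smooth_trajectory(res.f, window), label=name)
        ax_err.plot(t[1:], smooth_trajectory(res.error, window), label=name)
    ax_err.axhline(threshold, color="grey", ls="--", lw=0.8)
    ax_path.set_ylabel("focal power")
    ax_path.set_ylim(-0.02, 1.02)
    ax_err.set_ylabel("|f* - f|")
    ax_err.set_xlabel("frame")
    ax_path.legend(fontsize=8)
    return axes
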