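"""Minimal plotting helpers (unstyled): occupancy curves and window distances."""

from __future__ import annotations

import numpy as np

from .staging import StagePlan, stage_occupancy


def plot_occupancy(plan: StagePlan, rates, t_max: float = 10.0, ax=None):
    """Stage occupancy probabilities over time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ts = np.linspace(plan.start_time, t_max, 200)
    occ = stage_occupancy(plan, rates, ts)
    for k, label in enumerate(plan.stage_labels):
        ax.plot(ts, occ[:, k], label=label)
    ax.set_xlabel("relative time")
    ax.set_ylabel("stage probability")
    ax.legend(fontsize="small")
    return ax


def plot_window_distances(mean_distances, ax=None):
    """Bar plot of mean per-window curve distances (one series per group pair)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    arr = np.atleast_2d(np.asarray(mean_distances, float))
    x = np.arange(1, arr.shape[1] + 1)
    width = 0.8 / arr.shape[0]
    for i, row in enumerate(arr):
        ax.bar(x + (i - arr.shape[0] / 2 + 0.5) * width, row, width=width)
    ax.set_xlabel("time window")
    ax.set_ylabel("mean distance")
    return ax
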