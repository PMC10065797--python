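"""Plotting helpers for trajectories and heat maps (matplotlib, Agg-safe)."""

from __future__ import annotations

import numpy as np


def plot_trajectory(norm, fit=None, ax=None):
    """Normalized channels and ratio of one track, with the fitted curve."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(norm.times_min, norm.norm_green, color="tab:green",
            label="Norm.G (dome-MESO-GFP)")
    ax.plot(norm.times_min, norm.norm_red, color="tab:red",
            label="Norm.R (eater-dsRed)")
    ax2 = ax.twinx()
    ax2.plot(norm.times_min, norm.ratio, color="black", lw=0.8,
             label="dsRed:GFP ratio")
    if fit is not None and fit.logistic_params is not None \
            and fit.trajectory_class == "sigmoid":
        from .differentiation import logistic4
        t = np.asarray(norm.times_min)
        ax2.plot(t, logistic4(t, *fit.logistic_params), ls="--",
                 color="gray", label="logistic fit")
        if fit.fast_phase:
            ax2.axvspan(*fit.fast_phase, alpha=0.15, color="orange")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("normalized intensity")
    ax2.set_ylabel("dsRed:GFP ratio")
    ax.legend(loc="upper left", fontsize=8)
    return ax


def plot_heatmap(heatmap, ax=None, title=None):
    """Event-count grid with row 0 (nearest the heart tube) at the left."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(heatmap.counts.T, origin="lower", cmap="inferno")
    ax.set_xlabel("distance from heart tube (bin)")
    ax.set_ylabel("position along tube (bin)")
    if title:
        ax.set_title(title)
    plt.colorbar(im, ax=ax, label="events")
    return ax
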