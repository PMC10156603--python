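"""Matplotlib helpers for the standard smFRET summary figures."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_transition_density", "plot_population_histogram", "plot_trace"]


def plot_transition_density(hist: np.ndarray, edges: np.ndarray, ax=None):
    """Transition density plot: FRET before vs FRET after each transition."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.pcolormesh(edges, edges, hist.T, cmap="viridis")
    ax.plot([0, 1], [0, 1], color="w", lw=0.5, ls="--")
    ax.set_xlabel("FRET before")
    ax.set_ylabel("FRET after")
    ax.set_aspect("equal")
    return ax


def plot_population_histogram(pop: dict, ax=None, normalized: bool = True):
    """Time-resolved population histogram (output of population_histogram)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    z = pop["normalized"] if normalized else pop["counts"]
    centers = 0.5 * (pop["fret_edges"][:-1] + pop["fret_edges"][1:])
    ax.pcolormesh(pop["times"], centers, z.T, cmap="magma", shading="nearest")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("FRET")
    return ax


def plot_trace(trace, fret=None, ideal=None, ax=None):
    """Donor/acceptor intensities with optional FRET and idealized path."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, axes = plt.subplots(2, 1, sharex=True, figsize=(7, 4))
    else:
        axes = ax
    t = trace.times
    axes[0].plot(t, trace.donor, color="tab:green", lw=0.6, label="donor")
    axes[0].plot(t, trace.acceptor, color="tab:red", lw=0.6, label="acceptor")
    axes[0].set_ylabel("intensity (a.u.)")
    axes[0].legend(loc="upper right", fontsize=8)
    if fret is not None:
        axes[1].plot(t[: len(fret)], fret, color="tab:blue", lw=0.6)
    if ideal is not None:
        axes[1].plot(
            t[: ideal.n_frames], ideal.fitted_fret(), color="tab:red", lw=1.0
        )
    axes[1].set_ylim(-0.1, 1.1)
    axes[1].set_xlabel("time (s)")
    axes[1].set_ylabel("FRET")
    return axes
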