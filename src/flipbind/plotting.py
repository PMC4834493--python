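"""Quick-look plots for profiles, sensorgrams and per-residue observables."""

from __future__ import annotations

import numpy as np


def plot_fes(fes, ax=None, label=None, critical_points=None):
    """Free-energy profile with optional error band and labelled extrema."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(fes.grid, fes.F, label=label)
    if fes.err is not None:
        ax.fill_between(fes.grid, fes.F - fes.err, fes.F + fes.err, alpha=0.3)
    if critical_points is not None:
        for p in critical_points.minima + critical_points.saddles:
            ax.annotate(p.label, (p.s, p.F), textcoords="offset points", xytext=(0, 6))
    ax.set_xlabel("s (path progress)")
    ax.set_ylabel("F (kcal/mol)")
    if label:
        ax.legend()
    return ax


def plot_sensorgram(data, fit=None, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(data["time_s"], data["response_RU"], ".", ms=2, alpha=0.6)
    if fit is not None:
        t = np.asarray(data["time_s"])
        ax.plot(t, fit.r0 * np.exp(-fit.k_d * t) + fit.baseline, "r-", lw=1.5,
                label=f"k_d = {fit.k_d:.3g} s$^{{-1}}$")
        ax.legend()
    ax.set_xlabel("time (s)")
    ax.set_ylabel("response (RU)")
    return ax


def plot_per_residue(df, column, ax=None, ylabel=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 2.5))
    ax.bar(df["residue"], df[column], width=1.0)
    ax.set_xlabel("residue")
    ax.set_ylabel(ylabel or column)
    return ax
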