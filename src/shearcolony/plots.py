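"""Minimal plotting helpers (matplotlib, headless backend)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from shearcolony.growth import GrowthModelFit, effective_growth_from_fraction

__all__ = ["plot_growth_model", "plot_population_series"]


def plot_growth_model(fit: GrowthModelFit, path) -> None:
    """Measured (eta_eff, f) points with the fitted model curve overlaid."""
    fig, ax = plt.subplots(figsize=(4, 3))
    f_grid = np.linspace(0.51, 1.0, 200)
    ax.plot([effective_growth_from_fraction(f, fit.tau_bar_d)
             for f in f_grid], f_grid, "--",
            label=f"model, tau = {fit.tau_bar_d:.0f} min")
    fs = [f for f, _ in fit.data]
    etas = [e for _, e in fit.data]
    ax.plot(etas, fs, "o", label="measured")
    ax.set_xlabel(r"$\eta_{\rm eff}$ (h$^{-1}$)")
    ax.set_ylabel("fraction of dividers $f$")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_population_series(series, path, log: bool = True) -> None:
    """Attached count versus time, with birth-class decomposition if present."""
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(series.times, series.N, "k-", label="N")
    if series.birth_class_counts is not None:
        cmap = plt.get_cmap("coolwarm")
        n_cls = series.birth_class_counts.shape[1]
        for c in range(n_cls):
            ax.plot(series.times, series.birth_class_counts[:, c],
                    color=cmap(c / max(n_cls - 1, 1)), lw=0.8)
    if log:
        ax.set_yscale("log")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("attached cells")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
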