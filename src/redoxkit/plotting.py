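"""Plotting helpers for the analysis results.

All functions draw onto a provided (or freshly created) matplotlib Axes
and return it; figures are never shown or saved here.
"""

from __future__ import annotations

import matplotlib.pyplot as plt
import numpy as np

from .binding import BindingKineticsResults
from .datatypes import BlinkMap, ProbeRetractionCurve, Sensogram
from .forcespec import BellEvansResults
from .simulate.spr import langmuir_response


def plot_iz_ensemble(curves: list[ProbeRetractionCurve], ax=None, **kwargs):
    """Semi-logarithmic I-z overlay of a curve ensemble."""
    ax = ax or plt.gca()
    for c in curves:
        ax.semilogy(c.z, c.current, alpha=kwargs.pop("alpha", 0.3), lw=0.8)
    ax.set_xlabel("z (nm)")
    ax.set_ylabel("I (nA)")
    return ax


def plot_blink_map(blink_map: BlinkMap, ax=None):
    """Normalized 2D blink histogram (max bin = 100 counts)."""
    ax = ax or plt.gca()
    mesh = ax.pcolormesh(
        blink_map.time_axis, blink_map.current_axis, blink_map.counts.T,
        shading="auto",
    )
    plt.colorbar(mesh, ax=ax, label="normalized counts")
    ax.set_xlabel("time since blink onset (s)")
    ax.set_ylabel("I$_{blink}$ (nA)")
    return ax


def plot_dfs(results: BellEvansResults, rates, forces, ax=None):
    """Most-probable force vs loading rate (log axis) with the fitted line."""
    ax = ax or plt.gca()
    rates = np.asarray(rates, dtype=float)
    ax.semilogx(rates, forces, "o")
    grid = np.geomspace(rates.min() / 1.5, rates.max() * 1.5, 100)
    ax.semilogx(grid, results.intercept + results.slope * np.log(grid), "-")
    ax.set_xlabel("loading rate (pN/s)")
    ax.set_ylabel("F* (pN)")
    return ax


def plot_sensograms(
    sensograms: list[Sensogram], fit: BindingKineticsResults | None = None, ax=None
):
    """Sensograms with, optionally, the fitted 1:1 model overlaid."""
    ax = ax or plt.gca()
    for s in sensograms:
        ax.plot(s.time, s.response, ".", ms=2, label=f"{s.concentration * 1e6:.3g} µM")
        if fit is not None:
            model = langmuir_response(
                s.time, s.concentration, fit.kon, fit.koff, fit.rmax,
                s.association_end,
            )
            ax.plot(s.time, model, "-", lw=1.2, color="k")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("response (RU)")
    ax.legend()
    return ax
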