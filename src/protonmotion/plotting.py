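"""Matplotlib summaries of a motion study: delta charts and DVH overlays."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import dvh

_DELTA_STYLE = {"dD100": "o-", "dD99": "s--", "dD95": "^:"}


def composite_delta_chart(reports: dict, tolerance: float = 2.0):
    """Bar chart of 4D-composite-vs-3D index changes per strategy."""
    fig, ax = plt.subplots(figsize=(6, 4))
    strategies = list(reports)
    width = 0.25
    x = np.arange(len(strategies))
    for k, (name, idx) in enumerate((("dD95", 0), ("dD99", 1), ("dD100", 2))):
        vals = [reports[s].composite.deltas[idx] for s in strategies]
        ax.bar(x + (k - 1) * width, vals, width, label=name[1:])
    ax.axhspan(-tolerance, tolerance, color="0.85", zorder=0)
    ax.set_xticks(x, strategies)
    ax.set_ylabel("4D dose $-$ 3D apparent dose (% of prescription)")
    ax.axhline(0, color="k", lw=0.5)
    ax.legend(frameon=False)
    fig.tight_layout()
    return fig


def phase_delta_chart(report, tolerance: float = 2.0):
    """Per-phase index changes for one strategy across the breathing cycle."""
    fig, ax = plt.subplots(figsize=(6, 4))
    labels = [p.label for p in report.phases]
    for name, idx in (("dD100", 2), ("dD99", 1), ("dD95", 0)):
        ax.plot(labels, [p.deltas[idx] for p in report.phases],
                _DELTA_STYLE[name], label=name[1:])
    ax.axhspan(-tolerance, tolerance, color="0.85", zorder=0)
    ax.set_xlabel("respiratory phase (%)")
    ax.set_ylabel("change vs 3D plan (% of prescription)")
    ax.set_title(report.strategy)
    ax.legend(frameon=False)
    fig.tight_layout()
    return fig


def dvh_overlay(doses: dict, mask, structure_name: str = "PTV"):
    """Cumulative DVH curves for several dose volumes over one structure."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, dose in doses.items():
        levels, frac = dvh(dose, mask)
        ax.plot(levels, 100 * frac, label=name)
    ax.set_xlabel("dose (% of prescription)")
    ax.set_ylabel(f"{structure_name} volume (%)")
    ax.legend(frameon=False)
    fig.tight_layout()
    return fig
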