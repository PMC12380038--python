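"""Minimal figure exports for simulation results and case diagnostics."""

from __future__ import annotations

import numpy as np


def plot_operating_characteristics(result, ax=None):
    """Type-I error (left) and RMSE (right) per method across the sweep.

    ``result`` is a :class:`~propp.simulation.SimulationResult`; returns the
    matplotlib figure.
    """
    import matplotlib.pyplot as plt

    t = result.table
    if ax is None:
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    else:
        axes = ax
        fig = axes[0].figure
    for metric, a in zip(("type_one_error", "rmse"), axes):
        for method, sub in t.groupby("method"):
            sub = sub.sort_values("sweep_value")
            a.plot(sub["sweep_value"], sub[metric], marker="o", label=method)
        a.set_xlabel("sweep value")
        a.set_ylabel(metric.replace("_", " "))
    axes[0].legend(fontsize="small")
    fig.tight_layout()
    return fig


def plot_propensity_distribution(lam, z, ax=None, bins=30):
    """Histogram of fitted membership probabilities by data source."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    lam, z = np.asarray(lam), np.asarray(z)
    edges = np.linspace(0, 1, bins + 1)
    ax.hist(lam[z == 1], bins=edges, alpha=0.6, label="trial")
    ax.hist(lam[z == 0], bins=edges, alpha=0.6, label="external")
    ax.set_xlabel("propensity score $\\lambda$")
    ax.set_ylabel("patients")
    ax.legend()
    return ax.figure
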