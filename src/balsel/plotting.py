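"""Plotting helpers for Z-versus-time curves and single-gene power distributions."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .experiments import PowerResult, ZCurve

__all__ = ["plot_z_curve", "plot_power_distributions"]


def plot_z_curve(curve: ZCurve, focal: str = "pop1", bins=None, ax=None):
    """Z against divergence time (in N generations), one line per frequency bin."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    df = curve.frame[curve.frame.focal == focal]
    bins = bins if bins is not None else [b for b in df.bin.unique() if b != "all"]
    for label in bins:
        sub = df[df.bin == label].sort_values("time_n")
        ax.plot(sub.time_n, sub.z, marker="o", ms=3, label=label)
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("time since split (N generations)")
    ax.set_ylabel("Z")
    ax.legend(title="folded MAF bin", fontsize=8)
    return ax


def plot_power_distributions(result: PowerResult, ax=None, bins: int = 40):
    """Overlaid per-replicate Z histograms with and without balancing selection."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.hist(result.z_without, bins=bins, alpha=0.5, density=True, label="no balancing")
    ax.hist(result.z_with, bins=bins, alpha=0.5, density=True, label="balancing")
    ax.axvline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("per-replicate Z (all frequencies)")
    ax.set_ylabel("density")
    ax.legend()
    return ax
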