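"""Matplotlib views of the three analyses (probe profiles, enrichment
scatter, ratio violins). Each function returns the figure for saving."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .forks import ForkProbe, fork_distance


def probe_profile(probe: ForkProbe, ax=None):
    """Raw and smoothed signal of one oriented probe, peak marked."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    x = np.arange(len(probe.raw)) * probe.bin_size / 1000.0
    ax.plot(x, probe.raw, lw=0.6, color="0.6", label="raw")
    if probe.smoothed is not None:
        ax.plot(x, probe.smoothed, lw=1.4, color="C0", label="loess")
        d = fork_distance(probe)
        if d is not None:
            ax.axvline(d / 1000.0, color="C3", ls="--", lw=0.8, label="fork distance")
    ax.set_xlabel("distance from origin (kb)")
    ax.set_ylabel("break-end count")
    ax.set_title(f"{probe.origin_id} ({probe.side})")
    ax.legend(frameon=False, fontsize=8)
    return ax.figure


def enrichment_scatter(results: pd.DataFrame, x_threshold: float = 1.0, y_threshold: float = 1.0, ax=None):
    """Dual-ratio enrichment scatter with the hit thresholds as dotted lines."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    hits = results["hit"] if "hit" in results else pd.Series(False, index=results.index)
    ax.scatter(results.loc[~hits, "x_enrichment"], results.loc[~hits, "y_enrichment"], s=8, c="0.7")
    ax.scatter(results.loc[hits, "x_enrichment"], results.loc[hits, "y_enrichment"], s=12, c="C3")
    ax.axvline(x_threshold, ls=":", c="k", lw=0.8)
    ax.axhline(y_threshold, ls=":", c="k", lw=0.8)
    ax.set_xlabel("log enrichment: treatment vs none (tagged)")
    ax.set_ylabel("log enrichment: tag vs no tag (treated)")
    return ax.figure


def ratio_violin(records_with_ratio: pd.DataFrame, ax=None):
    """Violin plot of nuclear/cytoplasmic ratios per group."""
    if ax is None:
        _, ax = plt.subplots(figsize=(3.5, 4))
    names = sorted(records_with_ratio["group"].unique())
    data = [records_with_ratio.loc[records_with_ratio["group"] == g, "nc_ratio"] for g in names]
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(range(1, len(names) + 1), names)
    ax.set_ylabel("nuclear / cytoplasmic ratio")
    return ax.figure
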