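"""Quick-look plots for tracks, MSD profiles and FRAP curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_tracks(tracks: pd.DataFrame, ax=None):
    """Overlay all trajectories, coloured by track id."""
    if ax is None:
        _, ax = plt.subplots()
    for _, g in tracks.groupby("track_id"):
        g = g.sort_values("frame")
        ax.plot(g["x_um"], g["y_um"], lw=0.8)
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_aspect("equal")
    return ax


def plot_msd(profile, ax=None, label: str | None = None):
    """MSD versus lag time on log-log axes."""
    if ax is None:
        _, ax = plt.subplots()
    ax.loglog(profile.lags_s, profile.msd_um2, "o-", ms=3, label=label)
    ax.set_xlabel("lag τ (s)")
    ax.set_ylabel("MSD (µm²)")
    if label:
        ax.legend()
    return ax


def plot_frap(curve, ax=None):
    """Normalized FRAP recovery with the bleach instant marked."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.time_s, curve.normalized, lw=1)
    ax.axvline(0.0, color="k", ls="--", lw=0.8)
    ax.axhline(1.0, color="grey", ls=":", lw=0.8)
    ax.set_xlabel("time after bleach (s)")
    ax.set_ylabel("F / F$_0$")
    return ax


def plot_nn_histogram(distances: np.ndarray, bin_width_um: float = 0.1, ax=None):
    """Nearest-neighbour distance histogram (100 nm bins by default)."""
    if ax is None:
        _, ax = plt.subplots()
    d = np.asarray(distances)
    bins = np.arange(0, d.max() + bin_width_um, bin_width_um)
    ax.hist(d, bins=bins, edgecolor="k", lw=0.3)
    ax.set_xlabel("nearest-neighbour distance (µm)")
    ax.set_ylabel("count")
    return ax
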