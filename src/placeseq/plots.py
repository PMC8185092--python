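"""Figure helpers: posterior heatmaps, slope profiles, bias profiles."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_posterior(posterior, position=None, ax=None):
    """Heatmap of the decoded posterior over time, optionally with the true path."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ax.imshow(
        posterior.probabilities.T,
        origin="lower",
        aspect="auto",
        extent=[posterior.centers[0], posterior.centers[-1], 0, 2 * np.pi],
        cmap="hot",
    )
    if position is not None:
        ax.plot(posterior.centers, position.angle_at(posterior.centers), "c-", lw=1)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("angle (rad)")
    return ax


def plot_slope_profile(profiles: dict, ax=None):
    """Mean sequence slope vs location-to-stop per condition, with CIs."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for label, df in profiles.items():
        ok = df["defined"]
        ax.errorbar(
            df.loc[ok, "location"],
            df.loc[ok, "mean_slope"],
            yerr=[
                df.loc[ok, "mean_slope"] - df.loc[ok, "ci_lo"],
                df.loc[ok, "ci_hi"] - df.loc[ok, "mean_slope"],
            ],
            label=label,
            capsize=3,
        )
    ax.set_xlabel("location relative to stop (sites)")
    ax.set_ylabel("sequence slope (rad/s)")
    ax.legend()
    return ax


def plot_bias_profile(bias, ax=None):
    """Terminal posterior sums by goal-aligned location vs the shuffle null."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.bar(bias.locations, bias.observed, color=np.where(bias.significant, "r", "0.6"))
    ax.plot(bias.locations, bias.null_hi, "k--", lw=1, label="97.5th pct null")
    ax.plot(bias.locations, bias.null_lo, "k:", lw=1, label="2.5th pct null")
    ax.set_xlabel("location relative to goal (sites)")
    ax.set_ylabel("terminal posterior sum")
    ax.legend()
    return ax
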