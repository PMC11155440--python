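"""Optional figures: aggregate psychometric curves, threshold bars, PSE scatter."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.stats import norm

from .psychfit import aggregate_proportions, fit_cumulative_gaussian

GROUP_COLORS = {"DD": "crimson", "control": "black"}


def _color(group: str) -> str:
    return GROUP_COLORS.get(group, "steelblue")


def plot_aggregate_curves(trials: pd.DataFrame, range_name: str, ax=None):
    """Proportion "long" vs duration (log axis) per group, with fitted curves
    and arrows marking each group's PSE."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    sub = trials[trials["range"] == range_name]
    for group, g in sub.groupby("group"):
        tab = aggregate_proportions(g)
        fit = fit_cumulative_gaussian(tab)
        c = _color(group)
        ax.plot(tab.durations, tab.k / tab.n, "o", color=c, ms=4, label=group)
        if fit.converged:
            xs = np.geomspace(tab.durations[0], tab.durations[-1], 200)
            ax.plot(xs, norm.cdf((np.log10(xs) - fit.mu) / fit.sigma), color=c, lw=1.5)
            ax.annotate(
                "",
                xy=(fit.pse, 0.5),
                xytext=(fit.pse, -0.02),
                arrowprops=dict(arrowstyle="->", color=c),
            )
    ax.set_xscale("log")
    ax.set_xlabel("duration (s)")
    ax.set_ylabel('proportion "long"')
    ax.set_title(range_name)
    ax.legend(frameon=False)
    return ax


def plot_threshold_bars(fits: pd.DataFrame, ax=None):
    """Group-mean Weber fractions per range with SEM error bars."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    good = fits[fits["converged"]]
    ranges = sorted(good["range"].unique())
    groups = sorted(good["group"].unique())
    width = 0.35
    for j, group in enumerate(groups):
        means, sems = [], []
        for rng_name in ranges:
            w = good.query("`range` == @rng_name and group == @group")["weber"]
            means.append(w.mean())
            sems.append(w.std(ddof=1) / np.sqrt(len(w)))
        x = np.arange(len(ranges)) + (j - (len(groups) - 1) / 2) * width
        ax.bar(x, means, width, yerr=sems, capsize=3, color=_color(group), label=group, alpha=0.85)
    ax.set_xticks(np.arange(len(ranges)), ranges)
    ax.set_ylabel("Weber fraction")
    ax.legend(frameon=False)
    return ax


def plot_pse_scatter(fits: pd.DataFrame, range_name: str, reference: float, ax=None):
    """Individual PSEs per group with the physical reference duration marked."""
    if ax is None:
        _, ax = plt.subplots(figsize=(3.5, 3.5))
    good = fits[(fits["converged"]) & (fits["range"] == range_name)]
    groups = sorted(good["group"].unique())
    rng = np.random.default_rng(0)  # jitter only
    for j, group in enumerate(groups):
        pse = good.loc[good["group"] == group, "pse_s"]
        x = j + rng.uniform(-0.08, 0.08, len(pse))
        ax.plot(x, pse, "d", color=_color(group), alpha=0.7)
        ax.plot([j - 0.2, j + 0.2], [pse.mean()] * 2, color=_color(group), lw=2)
    ax.axhline(reference, ls=":", color="gray")
    ax.set_xticks(range(len(groups)), groups)
    ax.set_ylabel("PSE (s)")
    ax.set_title(range_name)
    return ax


def save_study_figures(trials: pd.DataFrame, fits: pd.DataFrame, outdir: str | Path) -> list[Path]:
    """Write the standard study figures as PNGs; returns written paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for rng_name, sub in trials.groupby("range"):
        ax = plot_aggregate_curves(trials, rng_name)
        p = out / f"curves_{rng_name}.png"
        ax.figure.savefig(p, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
        written.append(p)
        ref = float(np.sqrt(sub["duration_s"].min() * sub["duration_s"].max()))
        ax = plot_pse_scatter(fits, rng_name, ref)
        p = out / f"pse_{rng_name}.png"
        ax.figure.savefig(p, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
        written.append(p)
    ax = plot_threshold_bars(fits)
    p = out / "thresholds.png"
    ax.figure.savefig(p, dpi=150, bbox_inches="tight")
    plt.close(ax.figure)
    written.append(p)
    return written
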