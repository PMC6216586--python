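"""Matplotlib figures for the standard outputs (Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_score_track(track: pd.DataFrame, threshold: float, path=None, window_label: str = "50 kb"):
    """Smoothed score track per chromosome with the peak-calling threshold."""
    chroms = list(dict.fromkeys(track["chrom"]))
    fig, axes = plt.subplots(
        1, len(chroms), figsize=(4 * len(chroms), 3), sharey=True, squeeze=False
    )
    for ax, chrom in zip(axes[0], chroms):
        sub = track[(track["chrom"] == chrom) & (~track["filtered"])]
        ax.plot(sub["pos"] / 1e6, sub["smoothed"], ".", ms=2, color="steelblue")
        ax.axhline(threshold, color="red", ls=":", lw=1)
        ax.set_xlabel(f"chr {chrom} (Mb)")
    axes[0][0].set_ylabel(f"{window_label} sliding median score")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_lifespan_curves(curves, path=None, log_cfu: bool = False):
    """Mean viability (or normalized log10 CFU) per day for each pool."""
    fig, ax = plt.subplots(figsize=(4, 3))
    for curve in curves:
        v = np.asarray(curve.viability, dtype=float)
        if log_cfu:
            with np.errstate(divide="ignore"):
                v = np.log10(np.where(v > 0, v, np.nan))
        ax.plot(curve.days, v, marker="o", ms=3, label=curve.label or None)
        if curve.viability_sd is not None and not log_cfu:
            ax.fill_between(
                curve.days, v - curve.viability_sd, v + curve.viability_sd, alpha=0.2
            )
    ax.set_xlabel("day")
    ax.set_ylabel("normalized log10 CFU" if log_cfu else "viability (fraction of day 0)")
    if any(c.label for c in curves):
        ax.legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_pleiotropy_scatter(records: pd.DataFrame, cutoff: float = 0.15, path=None):
    """Growth dAF vs lifespan dAF; antagonistic loci highlighted in red."""
    rec = records[records["informative"]]
    x = rec["lifespan_daf"].to_numpy(float)
    y = rec["growth_daf"].to_numpy(float)
    antag = (np.abs(x) > cutoff) & (np.abs(y) > cutoff) & (x * y < 0)
    fig, ax = plt.subplots(figsize=(3.5, 3.5))
    ax.scatter(x[~antag], y[~antag], s=4, color="gray", alpha=0.5)
    ax.scatter(x[antag], y[antag], s=6, color="red")
    for v in (cutoff, -cutoff):
        ax.axvline(v, color="k", lw=0.5, ls=":")
        ax.axhline(v, color="k", lw=0.5, ls=":")
    ax.set_xlabel("lifespan ΔAF (day 6 - day 0)")
    ax.set_ylabel("growth ΔAF (regrown - day 6)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
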