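"""Figure and CSV export helpers for the main read-outs."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .metrics import ContributionReport, FRCResult
from .phasor import PhasorHistogram

__all__ = ["plot_phasor_histogram", "plot_contribution_chart",
           "plot_frc_curve", "histogram_to_csv", "frc_to_csv"]


def plot_phasor_histogram(hist: PhasorHistogram, path,
                          log_scale: bool = True) -> Path:
    """Rainbow-coded phasor-plane occupancy with the universal circle."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    counts = hist.counts.T
    norm = matplotlib.colors.LogNorm(vmin=1) if log_scale else None
    ax.imshow(np.where(counts > 0, counts, np.nan), origin="lower",
              extent=(hist.g_edges[0], hist.g_edges[-1],
                      hist.s_edges[0], hist.s_edges[-1]),
              aspect="auto", cmap="turbo", norm=norm)
    phi = np.linspace(0, np.pi, 200)
    ax.plot(0.5 + 0.5 * np.cos(phi), 0.5 * np.sin(phi), "k--", lw=0.8)
    ax.set_xlabel("G")
    ax.set_ylabel("S")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_contribution_chart(report: ContributionReport, path) -> Path:
    """Bar chart of per-pair contribution means with SD whiskers;
    lifetime-separated pairs share a highlight color."""
    s = report.summary
    fig, ax = plt.subplots(figsize=(max(4, 0.45 * len(s)), 3.2))
    labels = [f"{h}→{n}" for h, n in zip(s.home, s.neighbor)]
    colors = ["tab:orange" if ls else "0.3" for ls in s.lifetime_separated]
    ax.bar(labels, 100 * s.contribution_mean,
           yerr=100 * s.contribution_sd.fillna(0.0), color=colors)
    ax.set_ylabel("contribution (%)")
    ax.tick_params(axis="x", rotation=90, labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_frc_curve(result: FRCResult, path) -> Path:
    fig, ax = plt.subplots(figsize=(4.5, 3))
    ax.plot(result.spatial_frequencies, result.correlation, lw=1)
    ax.axhline(result.threshold, color="r", ls="--", lw=0.8)
    if result.crossed:
        ax.axvline(1.0 / result.resolution, color="0.5", ls=":", lw=0.8)
        ax.set_title(f"FRC resolution {result.resolution:.0f} nm")
    ax.set_xlabel("spatial frequency (1/nm)")
    ax.set_ylabel("FRC")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def histogram_to_csv(hist: PhasorHistogram, path) -> Path:
    df = pd.DataFrame(hist.counts, index=pd.Index(hist.g_centers, name="g"),
                      columns=pd.Index(hist.s_centers, name="s"))
    df.to_csv(path, float_format="%.6g")
    return Path(path)


def frc_to_csv(result: FRCResult, path) -> Path:
    pd.DataFrame({"freq_per_nm": result.spatial_frequencies,
                  "frc": result.correlation}).to_csv(path, index=False,
                                                     float_format="%.6g")
    return Path(path)
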