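"""Matplotlib figures for agreement reports and rescore timelines."""

from __future__ import annotations

import os

import matplotlib

matplotlib.use("Agg")  # headless: figures go to files, never a display
import matplotlib.pyplot as plt
import numpy as np

from .stats import BlandAltmanResult, CohortReport


def bland_altman_plot(
    x, y, ba: BlandAltmanResult, path: str | os.PathLike,
    xlabel: str = "Mean immobility time (s)",
    ylabel: str = "Difference, scorer 1 − scorer 2 (s)",
) -> None:
    """Scatter of paired differences vs means with bias and 1.96·SD limits."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((x + y) / 2, x - y, s=14, color="k", alpha=0.7)
    ax.axhline(0, color="k", lw=0.8)
    ax.axhline(ba.bias, color="r", lw=1.2, label=f"bias = {ba.bias:.1f} s")
    for loa in (ba.loa_lower, ba.loa_upper):
        ax.axhline(loa, color="r", ls=":", lw=1.0)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def clip_histogram_plot(report: CohortReport, path: str | os.PathLike) -> None:
    """Bar chart of mean disagreement-clip counts per 5 s length bin, with
    one-sd whiskers above the mean."""
    lefts = [b for b, _, _ in report.clip_histogram]
    means = [m for _, m, _ in report.clip_histogram]
    sds = [s for _, _, s in report.clip_histogram]
    width = lefts[1] - lefts[0] if len(lefts) > 1 else 5.0
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar([l + width / 2 for l in lefts], means, width=width * 0.9,
           yerr=[[0.0] * len(sds), sds], capsize=3, color="0.4")
    ax.set_xlabel("Disagreement clip length (s)")
    ax.set_ylabel("Mean clips per trial")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def timeline_plot(tables: dict, path: str | os.PathLike) -> None:
    """Stacked mobility timelines, one lane per scorer, immobile shaded."""
    fig, axes = plt.subplots(len(tables), 1, figsize=(8, 1.2 * len(tables)),
                             sharex=True, squeeze=False)
    for ax, (label, table) in zip(axes[:, 0], tables.items()):
        for seg in table.segments:
            if seg.mobility_state == 0:
                ax.axvspan(seg.mark_sec, seg.mark_sec + seg.interval_sec,
                           color="0.3")
        ax.set_xlim(0, table.clock.duration_sec)
        ax.set_yticks([])
        ax.set_ylabel(label, rotation=0, ha="right", va="center")
    axes[-1, 0].set_xlabel("Time (s)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
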