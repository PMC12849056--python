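"""Matplotlib rendering of overlays, deconvolutions and replicate bar plots.

Every plot has a tidy-table twin in the library (overlay_table,
results_table, summary_table, DeconvolutionFit.curves_frame), so numbers
never have to be read off pixels. Files default to vector PDF.
"""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .align import AlignmentResult
from .core import Profile
from .quantify import SummaryRow

__all__ = ["overlay_plot", "bar_plot", "deconvolution_plot"]


def _save(fig, path):
    if path is not None:
        fig.savefig(Path(path), bbox_inches="tight")
        plt.close(fig)
    return fig


def overlay_plot(profiles: list[Profile], result: AlignmentResult, path=None, ax=None):
    """Aligned UV traces (solid) and fluorescence traces (dashed, right axis)."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(8, 4))
    else:
        fig = ax.figure
    ax2 = None
    for p in profiles:
        off = result.offsets[p.id]
        x = np.arange(len(p)) + off
        (line,) = ax.plot(x, p.uv, label=p.id)
        if p.fluor is not None:
            if ax2 is None:
                ax2 = ax.twinx()
                ax2.set_ylabel("fluorescence (a.u.)")
            ax2.plot(x, p.fluor, linestyle="--", color=line.get_color(), alpha=0.7)
    ax.axvline(result.aligned_x, color="grey", linestyle=":", linewidth=1)
    ax.set_xlabel("aligned sample index")
    ax.set_ylabel("UV absorbance (a.u.)")
    ax.legend(frameon=False, fontsize="small")
    return _save(fig, path)


def bar_plot(rows: list[SummaryRow], path=None, ax=None):
    """Grouped bar plot of means with sd error bars, one bar per condition
    within each region label."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 4))
    else:
        fig = ax.figure
    labels = sorted({r.region_label for r in rows})
    conditions = sorted({r.condition for r in rows})
    width = 0.8 / max(len(conditions), 1)
    for ci, cond in enumerate(conditions):
        xs, means, sds = [], [], []
        for li, label in enumerate(labels):
            for r in rows:
                if r.condition == cond and r.region_label == label:
                    xs.append(li + ci * width)
                    means.append(r.mean)
                    sds.append(r.sd)
        ax.bar(xs, means, width=width, yerr=sds, capsize=3, label=cond)
    ax.set_xticks([i + 0.4 - width / 2 for i in range(len(labels))])
    ax.set_xticklabels(labels)
    ax.set_ylabel("area (relative)" if any(r.relative_to for r in rows) else "area (a.u.)")
    ax.legend(frameon=False, fontsize="small")
    return _save(fig, path)


def deconvolution_plot(fit, path=None, ax=None):
    """Observed region signal, per-peak Gaussians, and their sum."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 4))
    else:
        fig = ax.figure
    x = np.arange(fit.region.start, fit.region.end + 1)
    if fit.observed is not None:
        ax.plot(x, fit.observed, color="black", linewidth=1, label="signal")
    for k, p in enumerate(fit.peaks, start=1):
        ax.plot(x, p(x), linestyle="--", linewidth=1, label=f"peak {k}")
    ax.plot(x, fit.fitted_curve, color="crimson", linewidth=1.5, label="model")
    ax.set_xlabel("sample index")
    ax.set_ylabel("baseline-subtracted signal (a.u.)")
    ax.legend(frameon=False, fontsize="small")
    return _save(fig, path)
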