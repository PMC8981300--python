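"""Plot helpers: VAF dot plots, per-variant trajectories, AI-vs-logR maps.

All functions draw on a supplied or fresh matplotlib Axes and return the
figure; callers decide whether to save.  The Agg backend is forced so the
package works headless.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .copynumber import GenomeSegment
from .deconvolution import DeconvolutionResult
from .model import VariantTable

__all__ = ["dot_plot", "variant_plot", "ai_logr_plot"]

_STATUS_COLORS = {"clonal": "#c0392b", "subclonal": "#2980b9"}


def dot_plot(result: DeconvolutionResult, ax=None):
    """Per-sample VAF dot plot colored by predicted clonality."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    samples = sorted({c.sample_id for c in result.calls})
    xpos = {s: i for i, s in enumerate(samples)}
    rng = np.random.default_rng(0)
    for c in result.calls:
        ax.scatter(xpos[c.sample_id] + rng.uniform(-0.18, 0.18), c.scaled_vaf,
                   s=12, alpha=0.7, color=_STATUS_COLORS.get(c.status, "gray"))
    ax.set_xticks(range(len(samples)), samples, rotation=45, ha="right")
    ax.set_ylabel("VAF (scaled)")
    ax.set_ylim(0, 1)
    for status, color in _STATUS_COLORS.items():
        ax.scatter([], [], color=color, label=status)
    ax.legend(frameon=False)
    return ax.figure


def variant_plot(result: DeconvolutionResult, variant_id: str, ax=None):
    """Trajectory of one variant's scaled VAF across samples."""
    calls = sorted((c for c in result.calls if c.variant_id == variant_id),
                   key=lambda c: c.sample_id)
    if not calls:
        raise KeyError(f"variant {variant_id!r} not in result")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    xs = [c.sample_id for c in calls]
    ys = [c.scaled_vaf for c in calls]
    ax.plot(range(len(xs)), ys, "-o", color="gray", mfc="none")
    for i, c in enumerate(calls):
        ax.annotate(c.status[:3], (i, ys[i]), textcoords="offset points",
                    xytext=(0, 6), fontsize=8,
                    color=_STATUS_COLORS.get(c.status, "gray"))
    ax.set_xticks(range(len(xs)), xs, rotation=45, ha="right")
    ax.set_ylabel("VAF (scaled)")
    ax.set_ylim(0, 1)
    ax.set_title(variant_id)
    return ax.figure


def ai_logr_plot(segments: list[GenomeSegment], ax=None):
    """Allelic imbalance vs mean logR, one point per segment, sized by
    number of sites and labeled with the fitted composition."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for seg in segments:
        ax.scatter(seg.ai_ratio, seg.mean_logr,
                   s=20 + seg.n_sites / 5, alpha=0.7,
                   color="#8e44ad" if seg.subclonal_flag else "#27ae60")
        if seg.composition:
            ax.annotate(seg.composition, (seg.ai_ratio, seg.mean_logr),
                        textcoords="offset points", xytext=(4, 4), fontsize=8)
    ax.set_xlabel("allelic imbalance ratio")
    ax.set_ylabel("mean logR")
    return ax.figure
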