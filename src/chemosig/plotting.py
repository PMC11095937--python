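"""Convenience plots: traces with stimulus bars, histograms with Gaussian
overlays, and box-whisker panels.  Plots are presentation aids only; all
quantitative output comes from the analysis modules."""

from __future__ import annotations

import numpy as np

from .protocol import K_LABEL, StimulusProtocol
from .stats import BoxStats, GaussianFit, IndexHistogram
from .traces import TraceSet


def _get_ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_trace(traces: TraceSet, protocol: StimulusProtocol, roi_id: str, ax=None):
    ax = _get_ax(ax)
    idx = list(traces.roi_ids).index(roi_id)
    ax.plot(traces.time_s, traces.dff[idx], lw=0.8, color="k")
    top = traces.dff[idx].max()
    for ev in protocol.events:
        color = "tab:red" if ev.label == K_LABEL else "tab:orange"
        ax.axvspan(ev.onset_s, ev.offset_s, color=color, alpha=0.3)
        ax.text(ev.onset_s, top, ev.label, fontsize=7, rotation=90, va="bottom")
    ax.set_xlabel("time (s)")
    ax.set_ylabel(r"$\Delta F/F$")
    ax.set_title(roi_id)
    return ax


def plot_histogram_fit(hist: IndexHistogram, fit: GaussianFit | None = None, ax=None):
    ax = _get_ax(ax)
    ax.bar(hist.bin_centers, hist.counts, width=hist.bin_width, color="0.6",
           edgecolor="0.3")
    if fit is not None:
        x = np.linspace(hist.bin_edges[0], hist.bin_edges[-1], 400)
        ax.plot(x, fit.predict(x), "k--", lw=1.2)
    ax.set_xlabel(hist.source)
    ax.set_ylabel("count")
    return ax


def plot_box(stats_list: list[BoxStats], labels: list[str] | None = None, ax=None):
    ax = _get_ax(ax)
    for i, bs in enumerate(stats_list):
        ax.add_patch(
            __import__("matplotlib.patches", fromlist=["Rectangle"]).Rectangle(
                (i - 0.3, bs.q1), 0.6, bs.q3 - bs.q1, fill=False
            )
        )
        ax.hlines(bs.median, i - 0.3, i + 0.3, color="tab:red")
        ax.vlines(i, bs.whisker_lo, bs.q1)
        ax.vlines(i, bs.q3, bs.whisker_hi)
        if bs.outliers.size:
            ax.plot([i] * bs.outliers.size, bs.outliers, "rx", ms=4)
    ax.set_xticks(range(len(stats_list)))
    if labels:
        ax.set_xticklabels(labels, rotation=45, ha="right")
    return ax
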