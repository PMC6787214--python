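"""Sliding-window mean / SD / coefficient-of-variation over box counts.

The classifier's input is the trend of CV = sigma/mu computed over a
sliding window of consecutive box counts (default width 20, stride 1).
Within a trend window mu and sigma are the first and second central
moments of the counts (population convention, divide by w); the
inferential statistics in :mod:`ecgpsr.evaluation` use the sample
convention instead.

A stride-1 window is essential: wider strides (or the non-overlapping
"static" windows provided for comparison) decorrelate consecutive CV
values and can step over a healthy-to-unhealthy transition entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .phase_space import BoxCountSeries

__all__ = ["CVTrace", "sliding_stats", "static_window_stats"]

logger = logging.getLogger(__name__)

DEFAULT_STATS_W = 20


@dataclass
class CVTrace:
    """Per-window mean, SD and CV of a box-count series."""

    means: np.ndarray
    sds: np.ndarray
    cvs: np.ndarray
    w: int
    kind: str
    step: int = 1

    def __post_init__(self):
        if not (len(self.means) == len(self.sds) == len(self.cvs)):
            raise ValueError("means/sds/cvs must have equal length")

    def __len__(self) -> int:
        return len(self.cvs)


def _stats(counts: np.ndarray, w: int, step: int, kind: str) -> CVTrace:
    windows = sliding_window_view(counts.astype(float), w)[::step]
    means = windows.mean(axis=1)
    sds = np.sqrt(((windows - means[:, None]) ** 2).mean(axis=1))
    cvs = np.zeros_like(means)
    nz = means != 0
    cvs[nz] = sds[nz] / means[nz]
    if np.any(~nz):
        logger.warning("sliding stats: %d window(s) with zero mean box "
                       "count; their CV is recorded as 0", int(np.sum(~nz)))
    return CVTrace(means=means, sds=sds, cvs=cvs, w=w, kind=kind, step=step)


def sliding_stats(counts: BoxCountSeries | np.ndarray,
                  w: int = DEFAULT_STATS_W,
                  kind: str | None = None) -> CVTrace:
    """Stride-1 sliding statistics: k counts yield k - w + 1 windows."""
    if isinstance(counts, BoxCountSeries):
        kind = kind or counts.kind
        arr = counts.counts
    else:
        arr = np.asarray(counts)
        kind = kind or "?"
    if w < 2:
        raise ValueError("stats window length w must be >= 2")
    if arr.size < w:
        raise ValueError(f"need at least w={w} counts, got {arr.size}")
    return _stats(arr, w, 1, kind)


def static_window_stats(counts: BoxCountSeries | np.ndarray,
                        w: int = DEFAULT_STATS_W,
                        kind: str | None = None) -> CVTrace:
    """Non-overlapping (stride = w) windows: floor(k/w) of them.

    Provided only for the sliding-vs-static comparison; the resulting CV
    sequence is too erratic to threshold reliably.
    """
    if isinstance(counts, BoxCountSeries):
        kind = kind or counts.kind
        arr = counts.counts
    else:
        arr = np.asarray(counts)
        kind = kind or "?"
    if w < 2:
        raise ValueError("stats window length w must be >= 2")
    if arr.size < w:
        raise ValueError(f"need at least w={w} counts, got {arr.size}")
    return _stats(arr, w, w, kind)


def trace_to_frame(trace: CVTrace):
    """CV trace as a DataFrame (window_index, mean, sd, cv)."""
    import pandas as pd

    return pd.DataFrame({
        "window_index": np.arange(len(trace)),
        "mean": trace.means,
        "sd": trace.sds,
        "cv": trace.cvs,
    })


def plot_trace(trace: CVTrace, path=None, title: str | None = None):
    """Plot mean / SD / CV as three stacked panels (optional helper)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(3, 1, sharex=True, figsize=(8, 6))
    for ax, (name, y) in zip(axes, [("mean", trace.means),
                                    ("SD", trace.sds),
                                    ("CV", trace.cvs)]):
        ax.plot(y)
        ax.set_ylabel(name)
    axes[-1].set_xlabel("window index")
    if title:
        axes[0].set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=100)
        plt.close(fig)
        return None
    return fig
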