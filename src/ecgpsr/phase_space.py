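"""Delay embedding, phase-portrait rasterization, and box counting.

A sliding window of W1 consecutive feature segments (default 20) is
concatenated into one series, embedded into the plane as the point set
(x(t), x(t-T)) for a fixed delay T (default 20 ms), and rasterized onto
an N x N occupancy grid over the unit square.  The number of occupied
("black") cells n_b is the box count of the portrait; its evolution as
the window slides across the record is the signal the classifier reads.

In ``line`` mode (default) every grid cell crossed by the trajectory
polyline is occupied — a supercover rasterization: a cell is black iff
the segment between two consecutive embedded points intersects the
closed cell square.  ``point`` mode marks only the cells containing the
embedded points themselves and is kept for sensitivity checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from .features import FeatureSegment

__all__ = [
    "IntervalWindow",
    "PhasePortrait",
    "BoxCountSeries",
    "make_interval_windows",
    "embed",
    "rasterize",
    "box_count_series",
]

logger = logging.getLogger(__name__)

DEFAULT_W1 = 20
DEFAULT_DELAY_MS = 20.0
DEFAULT_GRID_N = 100


@dataclass
class IntervalWindow:
    """W1 consecutive feature segments, concatenated into one series."""

    kind: str
    segments: list
    window_index: int

    @property
    def series(self) -> np.ndarray:
        return np.concatenate([s.samples for s in self.segments])

    @property
    def beat_indices(self) -> list[int]:
        return [s.beat_index for s in self.segments]


@dataclass
class PhasePortrait:
    """An N x N boolean occupancy grid with its box counts."""

    grid: np.ndarray
    delay_samples: int
    grid_n: int

    @property
    def n_black(self) -> int:
        return int(np.count_nonzero(self.grid))

    @property
    def n_white(self) -> int:
        return self.grid_n * self.grid_n - self.n_black

    def to_pgm(self, path) -> None:
        """Write as a binary PGM (P5) image, black trajectory on white."""
        img = np.where(self.grid, 0, 255).astype(np.uint8)
        with open(path, "wb") as fh:
            fh.write(f"P5\n{self.grid_n} {self.grid_n}\n255\n".encode())
            fh.write(np.flipud(img.T).tobytes())

    def to_png(self, path) -> None:
        from PIL import Image

        img = np.where(self.grid, 0, 255).astype(np.uint8)
        Image.fromarray(np.flipud(img.T), mode="L").save(path)


@dataclass
class BoxCountSeries:
    """Ordered box counts, one per phase portrait."""

    counts: np.ndarray
    kind: str

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("box counts must be non-negative")

    @property
    def k(self) -> int:
        return self.counts.size


def make_interval_windows(segments: Sequence[FeatureSegment],
                          w1: int = DEFAULT_W1,
                          step: int = 1) -> list[IntervalWindow]:
    """Sliding windows of ``w1`` consecutive segments with stride ``step``.

    For n segments the number of windows is floor((n - w1)/step) + 1
    (0 if n < w1); with the defaults (w1=20, step=1) consecutive windows
    overlap in 19 segments.
    """
    if w1 < 1 or step < 1:
        raise ValueError("w1 and step must be >= 1")
    segments = list(segments)
    n = len(segments)
    out = []
    for j, start in enumerate(range(0, n - w1 + 1, step)):
        segs = segments[start:start + w1]
        out.append(IntervalWindow(kind=segs[0].kind, segments=segs,
                                  window_index=j))
    return out


def embed(series, delay_ms: float = DEFAULT_DELAY_MS,
          fs: float | None = None) -> np.ndarray:
    """Delay-embed a series into (L - T) planar points (x(t), x(t-T)).

    ``series`` may be an :class:`IntervalWindow` (fs taken from its
    segments) or a plain array (fs required).  Point j is
    ``(series[j+T], series[j])`` with T = round(delay_ms * fs / 1000).
    """
    if isinstance(series, IntervalWindow):
        if fs is None:
            fs = series.segments[0].fs
        x = series.series
    else:
        if fs is None:
            raise ValueError("fs is required when embedding a plain array")
        x = np.asarray(series, dtype=float)
    delay = int(round(delay_ms * fs / 1000.0))
    if delay < 1:
        raise ValueError(f"delay of {delay_ms} ms is < 1 sample at fs={fs}")
    if x.size <= delay:
        raise ValueError("segment shorter than delay")
    return np.column_stack([x[delay:], x[:-delay]])


@njit(cache=True)
def _seg_hits_cell(x0, y0, x1, y1, cx0, cy0, cx1, cy1,
                   open_x, open_y):  # pragma: no cover
    """Does the segment meet the half-open cell [cx0,cx1) x [cy0,cy1)?

    Liang-Barsky clipping against the closed square, then the midpoint of
    the clipped interval is tested against the open upper edges
    (``open_*`` is False for the grid's last row/column, which is closed
    at 1.0).
    """
    dx = x1 - x0
    dy = y1 - y0
    t0 = 0.0
    t1 = 1.0
    for axis in range(2):
        if axis == 0:
            p_lo, p_hi, d, o = cx0, cx1, dx, x0
        else:
            p_lo, p_hi, d, o = cy0, cy1, dy, y0
        if d == 0.0:
            if o < p_lo or o > p_hi:
                return False
        else:
            ta = (p_lo - o) / d
            tb = (p_hi - o) / d
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
            if t0 > t1:
                return False
    tm = 0.5 * (t0 + t1)
    mx = x0 + tm * dx
    my = y0 + tm * dy
    if open_x and mx >= cx1:
        return False
    if open_y and my >= cy1:
        return False
    return True


@njit(cache=True)
def _raster_line(xs, ys, n, grid):  # pragma: no cover
    inv = float(n)
    for k in range(xs.size - 1):
        x0, y0, x1, y1 = xs[k], ys[k], xs[k + 1], ys[k + 1]
        i0 = min(int(x0 * inv), n - 1)
        j0 = min(int(y0 * inv), n - 1)
        i1 = min(int(x1 * inv), n - 1)
        j1 = min(int(y1 * inv), n - 1)
        ia, ib = (i0, i1) if i0 <= i1 else (i1, i0)
        ja, jb = (j0, j1) if j0 <= j1 else (j1, j0)
        if ia == ib and ja == jb:
            grid[ia, ja] = True
            continue
        for i in range(ia, ib + 1):
            for j in range(ja, jb + 1):
                if grid[i, j]:
                    continue
                if _seg_hits_cell(x0, y0, x1, y1,
                                  i / inv, j / inv,
                                  (i + 1) / inv, (j + 1) / inv,
                                  i < n - 1, j < n - 1):
                    grid[i, j] = True


@njit(cache=True)
def _raster_points(xs, ys, n, grid):  # pragma: no cover
    for k in range(xs.size):
        i = min(int(xs[k] * n), n - 1)
        j = min(int(ys[k] * n), n - 1)
        grid[i, j] = True


def rasterize(pairs: np.ndarray, grid_n: int = DEFAULT_GRID_N,
              mode: str = "line", delay_samples: int = 0) -> PhasePortrait:
    """Rasterize embedded points onto an N x N grid over [0, 1]^2.

    Cells are half-open ``[i/N, (i+1)/N)`` with the coordinate 1.0 mapped
    into the last cell.  All coordinates must lie in [0, 1] (the pipeline
    normalizes the record first).
    """
    if grid_n < 2:
        raise ValueError("grid_n must be >= 2")
    if mode not in ("line", "point"):
        raise ValueError("mode must be 'line' or 'point'")
    pairs = np.asarray(pairs, dtype=float).reshape(-1, 2)
    grid = np.zeros((grid_n, grid_n), dtype=np.bool_)
    if pairs.size:
        if pairs.min() < 0.0 or pairs.max() > 1.0:
            raise ValueError("coordinates outside [0, 1]: normalize the "
                             "signal before embedding")
        xs = np.ascontiguousarray(pairs[:, 0])
        ys = np.ascontiguousarray(pairs[:, 1])
        if mode == "line":
            _raster_line(xs, ys, grid_n, grid)
            _raster_points(xs, ys, grid_n, grid)
        else:
            _raster_points(xs, ys, grid_n, grid)
    return PhasePortrait(grid=grid, delay_samples=delay_samples, grid_n=grid_n)


def box_count_series(windows: Sequence[IntervalWindow],
                     delay_ms: float = DEFAULT_DELAY_MS,
                     fs: float | None = None,
                     grid_n: int = DEFAULT_GRID_N,
                     mode: str = "line") -> BoxCountSeries:
    """Box-count every window's phase portrait, preserving order.

    Windows whose concatenated series is not longer than the delay are
    dropped with a warning; if every window is too short this is an error.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("no windows to box-count")
    counts = []
    dropped = 0
    for w in windows:
        try:
            pairs = embed(w, delay_ms=delay_ms, fs=fs)
        except ValueError:
            dropped += 1
            continue
        f = fs if fs is not None else w.segments[0].fs
        delay = int(round(delay_ms * f / 1000.0))
        counts.append(rasterize(pairs, grid_n=grid_n, mode=mode,
                                delay_samples=delay).n_black)
    if dropped:
        logger.warning("box_count_series: dropped %d window(s) shorter "
                       "than the delay", dropped)
    if not counts:
        raise ValueError("all windows shorter than the delay")
    return BoxCountSeries(counts=np.asarray(counts, dtype=np.int64),
                          kind=windows[0].kind)
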